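import numpy as np
import pytest

from ecgfb.records import ECGRecord, STANDARD_LEADS


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_record(n_samples: int, n_leads: int = 12, fs: float = 500.0,
                labels=frozenset(), seed: int = 0, record_id: str = "R0") -> ECGRecord:
    """A random-signal record, handy where morphology is irrelevant."""
    gen = np.random.default_rng(seed)
    lead_names = (STANDARD_LEADS[:n_leads] if n_leads <= 12
                  else tuple(f"ch{i}" for i in range(n_leads)))
    return ECGRecord(
        record_id=record_id,
        signal=gen.normal(size=(n_samples, n_leads)),
        fs=fs,
        lead_names=lead_names,
        labels=labels,
    )


@pytest.fixture
def random_record():
    return make_record(5000)
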