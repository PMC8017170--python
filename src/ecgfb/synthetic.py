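"""Synthetic multi-lead ECG corpus with class-dependent morphology.

Records are built from per-beat templates — a Gaussian P wave, a triangular
QRS complex and a Gaussian T wave — repeated at (possibly irregular) RR
intervals and projected onto 12 leads through fixed per-lead gain/polarity
vectors.  Each abnormality perturbs the defining feature a cardiologist
would look for:

================  ====================================================
AF                highly irregular RR (high coefficient of variation),
                  absent P waves
I-AVB             lengthened P-to-QRS (PR) delay
LBBB / RBBB       widened QRS, lead-dependent polarity flips
PAC / PVC         interspersed premature beats (narrow / wide + tall)
STD / STE         constant negative / positive ST-segment offset
Normal            regular RR, standard template
================  ====================================================

On top of the clean signal the generator adds baseline wander (slow
sinusoid), powerline interference (50 Hz by default) and white noise.
This is a template synthesiser, not a biophysical simulator: classes are
separable by construction, which is exactly what the downstream smoke
experiments need; it makes no claim of clinical fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import DEFAULT_CLASSES, ECGRecord, STANDARD_LEADS

# Per-lead gain applied to the P/QRS/T template (rough limb/chest polarity
# pattern; lead aVR conventionally inverted).
_LEAD_GAINS = np.array(
    [0.6, 1.0, 0.5, -0.8, 0.4, 0.7, -0.5, 0.9, 1.1, 1.2, 1.0, 0.9]
)

# Leads whose QRS polarity flips under a bundle-branch block.
_LBBB_FLIP = np.array([0, 4, 10, 11])   # lateral leads I, aVL, V5, V6
_RBBB_FLIP = np.array([6, 7])           # right precordial V1, V2

#: Class prevalences loosely matching a CPSC-like imbalance, remainder Normal.
DEFAULT_CLASS_MIX: dict[str, float] = {
    "AF": 0.16, "I-AVB": 0.10, "LBBB": 0.03, "PAC": 0.08, "PVC": 0.09,
    "RBBB": 0.24, "STD": 0.11, "STE": 0.03,
}

# Second labels are only drawn from clinically co-occurring pairs
# (e.g. AF with a bundle-branch block); Normal never co-occurs.
LABEL_COMPATIBILITY: dict[str, tuple[str, ...]] = {
    "AF": ("LBBB", "RBBB", "PAC", "PVC", "STD", "STE"),
    "I-AVB": ("LBBB", "RBBB", "PAC", "PVC", "STD", "STE"),
    "LBBB": ("AF", "I-AVB", "PAC", "PVC", "STD", "STE"),
    "RBBB": ("AF", "I-AVB", "PAC", "PVC", "STD", "STE"),
    "PAC": ("AF", "I-AVB", "LBBB", "RBBB", "PVC", "STD", "STE"),
    "PVC": ("AF", "I-AVB", "LBBB", "RBBB", "PAC", "STD", "STE"),
    "STD": ("AF", "I-AVB", "LBBB", "RBBB", "PAC", "PVC"),
    "STE": ("AF", "I-AVB", "LBBB", "RBBB", "PAC", "PVC"),
    "Normal": (),
}


@dataclass(frozen=True)
class NoiseSpec:
    baseline_wander_amp: float = 0.10   # mV
    baseline_wander_freq: float = 0.25  # Hz
    powerline_amp: float = 0.05         # mV
    powerline_freq: float = 50.0        # Hz (Chinese-hospital mains)
    white_sd: float = 0.02              # mV

    def __post_init__(self) -> None:
        if min(self.baseline_wander_amp, self.powerline_amp, self.white_sd) < 0:
            raise ValueError("noise amplitudes must be non-negative")


@dataclass(frozen=True)
class SyntheticConfig:
    fs: float = 500.0
    leads: int = 12
    duration_range: tuple[float, float] = (6.0, 60.0)
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    multilabel_rate: float = 0.07
    noise: NoiseSpec = NoiseSpec()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_range[0] <= 0 or self.duration_range[1] < self.duration_range[0]:
            raise ValueError(f"bad duration range {self.duration_range}")
        total = sum(self.class_mix.values())
        if total > 1.0 + 1e-9:
            raise ValueError(f"class prevalences sum to {total} > 1")
        unknown = set(self.class_mix) - set(DEFAULT_CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in mix: {sorted(unknown)}")
        if not (0.0 <= self.multilabel_rate <= 1.0):
            raise ValueError("multilabel_rate must be a probability")


def _gaussian(t: np.ndarray, center: float, width: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - center) / width) ** 2)


def _triangle(t: np.ndarray, center: float, half_width: float, amp: float) -> np.ndarray:
    return amp * np.clip(1.0 - np.abs(t - center) / half_width, 0.0, None)


def _beat_template(fs: float, *, qrs_width_s: float, pr_s: float,
                   with_p: bool, st_offset: float, qrs_amp: float) -> np.ndarray:
    """One beat sampled at ``fs``: P wave, QRS triangle, ST segment, T wave."""
    length_s = pr_s + qrs_width_s + 0.32  # ST (~0.12 s) + T wave room
    n = int(round(length_s * fs))
    t = np.arange(n) / fs
    beat = np.zeros(n)
    if with_p:
        beat += _gaussian(t, pr_s * 0.45, 0.025, 0.15)
    qrs_center = pr_s + qrs_width_s / 2.0
    beat += _triangle(t, qrs_center, qrs_width_s / 2.0, qrs_amp)
    # small Q/S dips flanking the R peak
    beat -= _gaussian(t, pr_s, 0.01, 0.1 * qrs_amp)
    beat -= _gaussian(t, pr_s + qrs_width_s, 0.01, 0.15 * qrs_amp)
    st_start = pr_s + qrs_width_s
    t_center = st_start + 0.20
    beat += _gaussian(t, t_center, 0.04, 0.30)
    if st_offset:
        window = (t >= st_start) & (t <= t_center - 0.06)
        beat[window] += st_offset
    return beat


def _class_params(labels: frozenset[str]) -> dict:
    p = {
        "rr_mean": 0.8, "rr_cv": 0.02, "qrs_width": 0.08, "pr": 0.16,
        "with_p": True, "st_offset": 0.0, "qrs_amp": 1.0,
        "premature_rate": 0.0, "premature_kind": None,
        "qrs_flip_leads": np.array([], dtype=int),
    }
    if "AF" in labels:
        p.update(rr_cv=0.30, with_p=False)
    if "I-AVB" in labels:
        p.update(pr=0.30)
    if "LBBB" in labels:
        p.update(qrs_width=0.15, qrs_flip_leads=_LBBB_FLIP)
    if "RBBB" in labels:
        p.update(qrs_width=0.14, qrs_flip_leads=_RBBB_FLIP)
    if "PAC" in labels:
        p.update(premature_rate=0.18, premature_kind="narrow")
    if "PVC" in labels:
        p.update(premature_rate=0.18, premature_kind="wide")
    if "STD" in labels:
        p.update(st_offset=-0.18)
    if "STE" in labels:
        p.update(st_offset=0.22)
    return p


def generate_record(class_labels: set[str] | frozenset[str], duration_s: float,
                    config: SyntheticConfig = SyntheticConfig(),
                    seed: int = 0, record_id: str | None = None,
                    noiseless: bool = False) -> ECGRecord:
    """Synthesise one labelled multi-lead record.

    ``class_labels`` may be empty or contain several compatible
    abnormalities; ``{"Normal"}`` and ``set()`` both yield the standard
    morphology.  ``noiseless`` suppresses all additive noise (useful for
    oracle measurements of the defining feature).
    """
    labels = frozenset(class_labels)
    unknown = labels - set(DEFAULT_CLASSES)
    if unknown:
        raise ValueError(f"unknown label(s) {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    fs = config.fs
    n = int(round(duration_s * fs))
    p = _class_params(labels)

    base_beat = _beat_template(
        fs, qrs_width_s=p["qrs_width"], pr_s=p["pr"], with_p=p["with_p"],
        st_offset=p["st_offset"], qrs_amp=p["qrs_amp"])
    premature_beat = None
    if p["premature_kind"] == "narrow":
        premature_beat = _beat_template(fs, qrs_width_s=0.07, pr_s=0.10,
                                        with_p=True, st_offset=p["st_offset"],
                                        qrs_amp=0.9)
    elif p["premature_kind"] == "wide":
        premature_beat = _beat_template(fs, qrs_width_s=0.16, pr_s=0.02,
                                        with_p=False, st_offset=p["st_offset"],
                                        qrs_amp=1.5)

    trace = np.zeros(n)
    qrs_trace = np.zeros(n)  # QRS-only component, for polarity flips per lead
    pos = 0.0
    while pos * fs < n:
        premature = premature_beat is not None and rng.random() < p["premature_rate"]
        beat = premature_beat if premature else base_beat
        start = int(round(pos * fs))
        stop = min(start + len(beat), n)
        if stop > start:
            trace[start:stop] += beat[:stop - start]
            if len(p["qrs_flip_leads"]):
                qb = np.zeros_like(beat)
                w = int(round((p["pr"] + p["qrs_width"]) * fs))
                qb[:w] = beat[:w]
                qrs_trace[start:stop] += qb[:stop - start]
        rr = p["rr_mean"] * (0.6 if premature else 1.0)
        rr *= max(0.3, 1.0 + p["rr_cv"] * rng.standard_normal())
        pos += rr

    gains = _LEAD_GAINS[:config.leads].copy()
    signal = np.outer(trace, gains)
    if len(p["qrs_flip_leads"]):
        flips = p["qrs_flip_leads"][p["qrs_flip_leads"] < config.leads]
        # flip the QRS component only on the affected leads
        signal[:, flips] -= 2.0 * np.outer(qrs_trace, gains[flips])

    if not noiseless:
        t = np.arange(n) / fs
        ns = config.noise
        phase_bw, phase_pl = rng.uniform(0, 2 * np.pi, size=2)
        noise = (
            ns.baseline_wander_amp * np.sin(2 * np.pi * ns.baseline_wander_freq * t + phase_bw)
            + ns.powerline_amp * np.sin(2 * np.pi * ns.powerline_freq * t + phase_pl)
        )
        signal = signal + noise[:, None] + rng.normal(0.0, ns.white_sd, size=signal.shape)

    lead_names = (STANDARD_LEADS if config.leads == 12
                  else tuple(f"ch{i + 1}" for i in range(config.leads)))
    return ECGRecord(
        record_id=record_id or f"SYN{seed:06d}",
        signal=signal,
        fs=fs,
        lead_names=lead_names,
        labels=labels,
    )


def generate_corpus(n: int, config: SyntheticConfig = SyntheticConfig(),
                    noiseless: bool = False) -> list[ECGRecord]:
    """Generate ``n`` records with multinomial class counts per the mix.

    Prevalences in ``class_mix`` are per-class draw probabilities with the
    remainder assigned to Normal; a ``multilabel_rate`` fraction of
    abnormal records receive a second, compatible label.  Durations are
    uniform over the configured range.  Reproducible from ``config.seed``.
    """
    if n < 1:
        raise ValueError(f"corpus size must be >= 1, got {n}")
    rng = np.random.default_rng(config.seed)
    classes = list(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes])
    p_normal = 1.0 - probs.sum()
    draw_classes = classes + ["Normal"]
    draw_probs = np.append(probs, p_normal)

    records = []
    for i in range(n):
        primary = draw_classes[rng.choice(len(draw_classes), p=draw_probs)]
        labels = {primary}
        if primary != "Normal" and rng.random() < config.multilabel_rate:
            options = [c for c in LABEL_COMPATIBILITY.get(primary, ())
                       if c in config.class_mix or c == "Normal"]
            options = [c for c in options if c != "Normal"]
            if options:
                labels.add(options[rng.integers(len(options))])
        duration = rng.uniform(*config.duration_range)
        records.append(generate_record(
            labels, duration, config,
            seed=int(rng.integers(2 ** 31 - 1)),
            record_id=f"SYN{i:05d}", noiseless=noiseless))
    return records
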