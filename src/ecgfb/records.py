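"""Multi-lead ECG records and a CPSC-style on-disk dialect.

A record is a samples-by-leads matrix in millivolts plus a sampling rate,
lead names and a (possibly empty, possibly multi-element) set of diagnosis
labels.  On disk a record is a MAT container holding one numeric matrix
(variable ``val``) next to a small line-oriented header carrying the record
id, lead count, sampling rate, sample count and a ``#Dx:`` diagnosis line.
The dialect follows the CPSC convention in spirit; full WFDB parsing is out
of scope.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy.io import loadmat, savemat

#: The nine cardiac states of the CPSC 2018 corpus.
DEFAULT_CLASSES: tuple[str, ...] = (
    "AF", "I-AVB", "LBBB", "Normal", "PAC", "PVC", "RBBB", "STD", "STE",
)

#: Standard 12-lead names in conventional order.
STANDARD_LEADS: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

MAT_VARIABLE = "val"


class FormatError(ValueError):
    """Raised when an on-disk record violates the expected dialect."""


@dataclass
class ECGRecord:
    """One multi-lead ECG recording.

    Parameters
    ----------
    record_id : str
        Identifier, used as the file stem when written.
    signal : ndarray, shape (n_samples, n_leads)
        Voltages in millivolts, samples along axis 0.
    fs : float
        Sampling rate in Hz (CPSC records are 500 Hz).
    lead_names : sequence of str
        One name per signal column.
    labels : set of str
        Diagnosis classes present in the record; empty and multi-label
        sets are both legal.
    """

    record_id: str
    signal: np.ndarray
    fs: float = 500.0
    lead_names: tuple[str, ...] = STANDARD_LEADS
    labels: frozenset[str] = frozenset()
    sex: str | None = None
    age: str | None = None
    vocabulary: tuple[str, ...] = DEFAULT_CLASSES
    _extra: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError(
                f"signal must be 2-D (samples x leads), got shape {self.signal.shape}"
            )
        if self.signal.shape[0] < 1 or self.signal.shape[1] < 1:
            raise ValueError("signal needs at least one sample and one lead")
        if self.signal.shape[1] != len(self.lead_names):
            raise ValueError(
                f"{self.signal.shape[1]} leads but {len(self.lead_names)} lead names"
            )
        if not np.isfinite(self.signal).all():
            raise ValueError("signal contains non-finite values")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.labels = frozenset(self.labels)
        unknown = self.labels - set(self.vocabulary)
        if unknown:
            raise ValueError(
                f"labels {sorted(unknown)} not in class vocabulary {list(self.vocabulary)}"
            )

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_leads(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_signal(self, signal: np.ndarray) -> "ECGRecord":
        """Copy of this record with a replaced signal matrix."""
        return ECGRecord(
            record_id=self.record_id,
            signal=signal,
            fs=self.fs,
            lead_names=self.lead_names,
            labels=self.labels,
            sex=self.sex,
            age=self.age,
            vocabulary=self.vocabulary,
        )


def _orient_samples_major(mat: np.ndarray, samples_axis: int | None) -> np.ndarray:
    """Return the matrix with samples along axis 0.

    Orientation is inferred by the rule "the longer axis is samples" —
    ECG records always have far more samples than leads.  ``samples_axis``
    overrides the inference.
    """
    if samples_axis is not None:
        if samples_axis not in (0, 1):
            raise ValueError("samples_axis must be 0 or 1")
        return mat if samples_axis == 0 else mat.T
    return mat if mat.shape[0] >= mat.shape[1] else mat.T


def read_cpsc_record(
    mat_path: str | os.PathLike,
    header_path: str | os.PathLike,
    vocabulary: tuple[str, ...] = DEFAULT_CLASSES,
    samples_axis: int | None = None,
) -> ECGRecord:
    """Read a MAT + header pair into an :class:`ECGRecord`.

    The MAT file must contain one numeric matrix; the signal is oriented
    samples-major regardless of on-disk orientation (longer axis wins,
    override with ``samples_axis``).  Diagnosis labels come from the
    header's ``#Dx:`` comment line.
    """
    mat_path, header_path = os.fspath(mat_path), os.fspath(header_path)
    if not os.path.exists(mat_path):
        raise FileNotFoundError(f"MAT file not found: {mat_path}")
    if not os.path.exists(header_path):
        raise FileNotFoundError(f"header file not found: {header_path}")
    try:
        contents = loadmat(mat_path)
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise FormatError(f"could not parse MAT file {mat_path}: {exc}") from exc
    arrays = {k: v for k, v in contents.items() if not k.startswith("__")}
    if MAT_VARIABLE in arrays:
        raw = arrays[MAT_VARIABLE]
    elif len(arrays) == 1:
        raw = next(iter(arrays.values()))
    else:
        raise FormatError(
            f"{mat_path} holds {sorted(arrays)}; expected one matrix "
            f"(or a variable named {MAT_VARIABLE!r})"
        )
    raw = np.asarray(raw)
    if raw.ndim != 2 or not np.issubdtype(raw.dtype, np.number):
        raise FormatError(
            f"{mat_path}: expected a 2-D numeric matrix, got dtype {raw.dtype}, "
            f"shape {raw.shape}"
        )
    signal = _orient_samples_major(raw.astype(float), samples_axis)

    meta = _parse_header(header_path)
    n_leads = meta.get("n_leads", signal.shape[1])
    if n_leads != signal.shape[1]:
        raise FormatError(
            f"{header_path} declares {n_leads} leads but matrix has "
            f"{signal.shape[1]} (after orientation)"
        )
    labels = frozenset(meta.get("labels", ()))
    unknown = labels - set(vocabulary)
    if unknown:
        raise FormatError(
            f"{header_path}: unknown label token(s) {sorted(unknown)}; "
            f"vocabulary is {list(vocabulary)}"
        )
    lead_names = meta.get("lead_names")
    if lead_names is None:
        lead_names = (
            STANDARD_LEADS if n_leads == 12
            else tuple(f"ch{i + 1}" for i in range(n_leads))
        )
    return ECGRecord(
        record_id=meta.get("record_id", os.path.splitext(os.path.basename(mat_path))[0]),
        signal=signal,
        fs=meta.get("fs", 500.0),
        lead_names=tuple(lead_names),
        labels=labels,
        sex=meta.get("sex"),
        age=meta.get("age"),
        vocabulary=vocabulary,
    )


def _parse_header(path: str) -> dict:
    meta: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty header")
    first = lines[0].split()
    if len(first) < 3:
        raise FormatError(
            f"{path}: header line must be 'id n_leads fs [n_samples]', got {lines[0]!r}"
        )
    meta["record_id"] = first[0]
    try:
        meta["n_leads"] = int(first[1])
        meta["fs"] = float(first[2])
        if len(first) > 3:
            meta["n_samples"] = int(first[3])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric header field in {lines[0]!r}") from exc
    for ln in lines[1:]:
        if ln.startswith("#Dx:"):
            tokens = [t.strip() for t in ln[len("#Dx:"):].split(",")]
            meta["labels"] = tuple(t for t in tokens if t)
        elif ln.startswith("#Sex:"):
            meta["sex"] = ln[len("#Sex:"):].strip() or None
        elif ln.startswith("#Age:"):
            meta["age"] = ln[len("#Age:"):].strip() or None
        elif ln.startswith("#Leads:"):
            meta["lead_names"] = tuple(
                t.strip() for t in ln[len("#Leads:"):].split(",") if t.strip()
            )
    return meta


def write_record(record: ECGRecord, directory: str | os.PathLike) -> tuple[str, str]:
    """Write ``record`` as a MAT + header pair under ``directory``.

    Returns the two file paths.  ``read_cpsc_record(*write_record(r, d))``
    reproduces the signal to numeric round-trip precision and the labels
    exactly.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    mat_path = os.path.join(directory, f"{record.record_id}.mat")
    hea_path = os.path.join(directory, f"{record.record_id}.hea")
    # CPSC stores leads x samples; do the same so round-trips exercise
    # the orientation inference.
    savemat(mat_path, {MAT_VARIABLE: record.signal.T})
    lines = [
        f"{record.record_id} {record.n_leads} {record.fs:g} {record.n_samples}",
        f"#Leads: {','.join(record.lead_names)}",
        f"#Dx: {','.join(sorted(record.labels))}",
    ]
    if record.sex:
        lines.append(f"#Sex: {record.sex}")
    if record.age:
        lines.append(f"#Age: {record.age}")
    with open(hea_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
    return mat_path, hea_path
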