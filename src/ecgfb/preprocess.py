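"""Denoising and length unification for multi-lead ECG.

Two length-unification strategies are provided:

* **Frame blocking** — the record is cut into a fixed number ``F_n`` of
  fixed-length frames (``F_l`` samples each) whose start-to-start lag, the
  frameshift ``F_s``, adapts to the record length ``S_l``::

      F_s = (S_l - F_l) / (F_n - 1)

  Consecutive frames overlap by ``f_o = F_l - F_s``, so the whole record is
  retained whenever ``S_l <= F_n * F_l`` and no tail is discarded.  Every
  record maps onto a tensor of shape ``(F_n, F_l, n_leads)``.

* **Truncate / zero-pad** — the common baseline: keep the first
  ``target_length`` samples or append zeros up to it.

Denoising is an 8th-order Butterworth lowpass at 35 Hz (most diagnostic ECG
energy lies between 0.1 and 35 Hz), applied per lead, zero-phase by default
(forward-backward, squaring the magnitude response but leaving waveform
morphology undistorted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .records import ECGRecord


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth lowpass design parameters."""

    order: int = 8
    cutoff_hz: float = 35.0
    kind: str = "lowpass"
    zero_phase: bool = True
    # Optional baseline-wander highpass (default off; the lowpass alone is
    # the stated denoising protocol).
    highpass_hz: float | None = None

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError(f"filter order must be >= 1, got {self.order}")
        if self.cutoff_hz <= 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff_hz}")
        if self.kind != "lowpass":
            raise ValueError(f"unsupported filter kind {self.kind!r}")


@dataclass(frozen=True)
class FrameConfig:
    """Frame-blocking constants: frame length F_l and frame count F_n."""

    frame_length: int = 2000
    frame_count: int = 10
    pad_value: float = 0.0

    def __post_init__(self) -> None:
        if self.frame_length < 1:
            raise ValueError(f"frame_length must be >= 1, got {self.frame_length}")
        if self.frame_count < 2:
            raise ValueError(f"frame_count must be >= 2, got {self.frame_count}")


@dataclass
class FrameBlock:
    """A record rendered as F_n frames of F_l samples per lead.

    ``data`` has shape ``(F_n, F_l, n_leads)``; ``offsets`` holds the F_n
    frame start indices into the (possibly zero-padded) source lead;
    ``nominal_shift`` is the real-valued frameshift F_s from the framing
    equation and ``overlap`` the identity f_o = F_l - F_s.
    """

    data: np.ndarray
    offsets: np.ndarray
    nominal_shift: float
    overlap: float
    source_id: str
    labels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.offsets = np.asarray(self.offsets, dtype=int)
        if self.data.ndim != 3:
            raise ValueError(f"frame tensor must be 3-D, got shape {self.data.shape}")
        if len(self.offsets) != self.data.shape[0]:
            raise ValueError("one offset per frame required")
        if self.offsets[0] != 0:
            raise ValueError("first frame must start at sample 0")
        if np.any(np.diff(self.offsets) < 0):
            raise ValueError("offsets must be non-decreasing")
        if abs(self.overlap - (self.data.shape[1] - self.nominal_shift)) > 1e-9:
            raise ValueError("overlap must equal F_l - F_s")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def design_lowpass(spec: FilterSpec, fs: float):
    """Design the Butterworth lowpass as second-order sections.

    DC gain is exactly 1 and the magnitude response is monotonically
    non-increasing (maximally flat design).
    """
    nyquist = fs / 2.0
    if spec.cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {spec.cutoff_hz} Hz must be below Nyquist {nyquist} Hz"
        )
    return sps.butter(spec.order, spec.cutoff_hz, btype="lowpass", fs=fs, output="sos")


def lowpass_response(spec: FilterSpec, fs: float, freqs_hz) -> np.ndarray:
    """|H(f)| of the single-pass design at the given frequencies (Hz)."""
    sos = design_lowpass(spec, fs)
    _, h = sps.sosfreqz(sos, worN=np.atleast_1d(np.asarray(freqs_hz, dtype=float)), fs=fs)
    return np.abs(h)


def denoise(record: ECGRecord, spec: FilterSpec = FilterSpec()) -> ECGRecord:
    """Lowpass-filter every lead of ``record`` independently.

    Zero-phase mode applies the design forward and backward (gain |H(f)|^2,
    no phase shift); causal mode applies it once.
    """
    sos = design_lowpass(spec, record.fs)
    x = record.signal
    if spec.zero_phase:
        # sosfiltfilt needs a minimum signal length for its edge padding.
        padlen = 3 * (2 * sos.shape[0] + 1)
        if x.shape[0] <= padlen:
            raise ValueError(
                f"record of {x.shape[0]} samples is too short for zero-phase "
                f"filtering (needs > {padlen}); pad the record or use causal mode"
            )
        y = sps.sosfiltfilt(sos, x, axis=0)
    else:
        y = sps.sosfilt(sos, x, axis=0)
    if spec.highpass_hz is not None:
        hp = sps.butter(2, spec.highpass_hz, btype="highpass", fs=record.fs, output="sos")
        y = sps.sosfiltfilt(hp, y, axis=0) if spec.zero_phase else sps.sosfilt(hp, y, axis=0)
    return record.with_signal(y)


def frame_shift(s_l: int, f_l: int, f_n: int) -> float:
    """Frameshift F_s = (S_l - F_l) / (F_n - 1).

    May be negative (record shorter than one frame) or exceed F_l (record
    longer than F_n frames laid end to end); :func:`frame_block` interprets
    both cases.
    """
    if f_n < 2:
        raise ValueError(f"frame count must be >= 2 (got {f_n}): framing equation divides by F_n - 1")
    return (s_l - f_l) / (f_n - 1)


def frame_offsets(s_l: int, config: FrameConfig) -> np.ndarray:
    """Integer frame start indices for a record of ``s_l`` samples.

    The ideal starts ``i * F_s`` are rounded to the nearest sample, which
    pins the first frame to 0 and the last frame's end to S_l exactly while
    deviating at most half a sample from the ideal grid.  Records shorter
    than one frame get all-zero offsets (frames coincide on the padded lead).
    """
    f_l, f_n = config.frame_length, config.frame_count
    if s_l <= f_l:
        return np.zeros(f_n, dtype=int)
    shift = frame_shift(s_l, f_l, f_n)
    return np.rint(np.arange(f_n) * shift).astype(int)


def frame_block(record: ECGRecord, config: FrameConfig = FrameConfig()) -> FrameBlock:
    """Render ``record`` as a ``(F_n, F_l, n_leads)`` frame-block tensor.

    Frame ``i`` of each lead is the contiguous slice starting at
    ``offsets[i]``.  For records of at least one frame length the first
    frame starts at 0 and the last ends exactly at the record end, so no
    tail sample is ever discarded; shorter records are right-padded with
    ``pad_value`` to one frame and replicated.
    """
    f_l, f_n = config.frame_length, config.frame_count
    s_l = record.n_samples
    x = record.signal
    if s_l < f_l:
        pad = np.full((f_l - s_l, record.n_leads), config.pad_value, dtype=x.dtype)
        x = np.vstack([x, pad])
    offsets = frame_offsets(s_l, config)
    shift = 0.0 if s_l <= f_l else frame_shift(s_l, f_l, f_n)
    data = np.stack([x[o:o + f_l] for o in offsets], axis=0)
    return FrameBlock(
        data=data,
        offsets=offsets,
        nominal_shift=shift,
        overlap=f_l - shift,
        source_id=record.record_id,
        labels=record.labels,
    )


def pad_or_truncate(record: ECGRecord, target_length: int = 20000) -> ECGRecord:
    """The common baseline: cut to, or zero-pad up to, ``target_length``.

    Records longer than the target keep their first ``target_length``
    samples; shorter ones get zeros appended.
    """
    if target_length < 1:
        raise ValueError(f"target_length must be >= 1, got {target_length}")
    x = record.signal
    if x.shape[0] > target_length:
        y = x[:target_length]
    elif x.shape[0] < target_length:
        pad = np.zeros((target_length - x.shape[0], record.n_leads), dtype=x.dtype)
        y = np.vstack([x, pad])
    else:
        return record
    return record.with_signal(y)


def block_from_fixed_length(record: ECGRecord, config: FrameConfig = FrameConfig(),
                            target_length: int | None = None) -> FrameBlock:
    """Frame tensor for the truncate/zero-pad baseline.

    The record is first unified to ``target_length`` (default
    ``F_n * F_l``, i.e. 20,000 samples with defaults) and then cut into
    F_n contiguous non-overlapping frames, giving the baseline the same
    tensor interface as frame blocking.
    """
    if target_length is None:
        target_length = config.frame_count * config.frame_length
    fixed = pad_or_truncate(record, target_length)
    return frame_block(fixed, config)
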