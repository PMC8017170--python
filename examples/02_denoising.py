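"""Denoising: the 8th-order Butterworth lowpass at 35 Hz.

Generates a noisy record (baseline wander + 50-Hz powerline + white noise)
and reports how much out-of-band energy the filter removes.
"""

import numpy as np

from ecgfb import FilterSpec, denoise, generate_record, lowpass_response

rec = generate_record({"Normal"}, 10.0, seed=3)
clean = denoise(rec, FilterSpec())

def band_power(sig, fs, lo, hi):
    spec = np.abs(np.fft.rfft(sig, axis=0)) ** 2
    freqs = np.fft.rfftfreq(sig.shape[0], 1.0 / fs)
    return spec[(freqs >= lo) & (freqs <= hi)].sum()

pl_before = band_power(rec.signal, rec.fs, 45, 55)
pl_after = band_power(clean.signal, rec.fs, 45, 55)
print(f"power in the 45-55 Hz band: {pl_before:9.1f} -> {pl_after:7.3f} "
      f"({pl_after / pl_before:.2e} of original)")
h = lowpass_response(FilterSpec(), rec.fs, [5.0, 35.0, 50.0])
print(f"|H| at 5 / 35 / 50 Hz: {h[0]:.4f} / {h[1]:.4f} / {h[2]:.4f}")
# The default zero-phase application squares these magnitudes, so the
# 50-Hz powerline survives with < 0.4 % of its amplitude while in-band
# ECG morphology is untouched (and not phase-shifted).
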