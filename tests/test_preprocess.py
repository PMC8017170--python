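"""Denoising filter and the two length-unification strategies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgfb.preprocess import (FilterSpec, FrameConfig, block_from_fixed_length,
                              denoise, design_lowpass, frame_block,
                              frame_offsets, frame_shift, lowpass_response,
                              pad_or_truncate)

from conftest import make_record


class TestLowpassDesign:
    def test_dc_gain_is_unity(self):
        assert lowpass_response(FilterSpec(), 500.0, [0.0])[0] == pytest.approx(1.0)

    def test_stopband_below_passband(self):
        h = lowpass_response(FilterSpec(), 500.0, [10.0, 100.0])
        assert h[1] < h[0]

    def test_cutoff_attenuation_is_minus_3db(self):
        # Butterworth single-pass |H| at the cutoff is 1/sqrt(2)
        h35 = lowpass_response(FilterSpec(), 500.0, [35.0])[0]
        assert 0.60 <= h35 <= 0.80
        assert h35 == pytest.approx(2 ** -0.5, abs=1e-6)

    def test_magnitude_monotone_nonincreasing(self):
        freqs = np.linspace(0.0, 250.0, 400)
        h = lowpass_response(FilterSpec(), 500.0, freqs)
        assert np.all(np.diff(h) <= 1e-12)

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            design_lowpass(FilterSpec(cutoff_hz=250.0), 500.0)

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError, match="order"):
            FilterSpec(order=0)


class TestDenoise:
    @staticmethod
    def _sine_record(freqs_amps, n=5000, fs=500.0):
        t = np.arange(n) / fs
        sig = sum(a * np.sin(2 * np.pi * f * t) for f, a in freqs_amps)
        rec = make_record(n, n_leads=1, fs=fs)
        return rec.with_signal(sig[:, None])

    def test_passband_sinusoid_preserved(self):
        rec = self._sine_record([(5.0, 1.0)])
        out = denoise(rec, FilterSpec())
        mid = out.signal[1000:4000, 0]  # avoid edge transients
        assert np.max(np.abs(mid)) == pytest.approx(1.0, rel=0.02)

    def test_stopband_sinusoid_suppressed(self):
        rec = self._sine_record([(5.0, 1.0), (50.0, 1.0)])
        out = denoise(rec, FilterSpec())
        # isolate the residual 50-Hz component by subtracting a clean 5-Hz fit
        t = np.arange(rec.n_samples) / rec.fs
        basis = np.column_stack([np.sin(2 * np.pi * 5 * t), np.cos(2 * np.pi * 5 * t)])
        resid = out.signal[:, 0] - basis @ np.linalg.lstsq(basis, out.signal[:, 0], rcond=None)[0]
        amp50 = 2 * np.abs(np.fft.rfft(resid[1000:4000])).max() / 3000
        assert amp50 < 0.01  # |H(50)|^2 of the zero-phase 8th-order design

    def test_zero_signal_maps_to_zero(self):
        rec = make_record(3000, n_leads=2).with_signal(np.zeros((3000, 2)))
        out = denoise(rec)
        np.testing.assert_array_equal(out.signal, 0.0)

    def test_leads_filtered_independently(self):
        from ecgfb.records import ECGRecord

        rec = self._sine_record([(5.0, 1.0)])
        two = ECGRecord("x", np.column_stack([rec.signal[:, 0],
                                              np.zeros(rec.n_samples)]),
                        fs=rec.fs, lead_names=("I", "II"))
        out = denoise(two)
        np.testing.assert_array_equal(out.signal[:, 1], 0.0)

    def test_too_short_record_suggests_padding(self):
        rec = make_record(20, n_leads=1)
        with pytest.raises(ValueError, match="pad"):
            denoise(rec)

    def test_shape_fs_labels_preserved(self):
        rec = make_record(4000, labels=frozenset({"AF"}))
        out = denoise(rec)
        assert out.signal.shape == rec.signal.shape
        assert out.fs == rec.fs and out.labels == rec.labels


class TestFrameShift:
    @pytest.mark.parametrize("s_l,expected", [
        (20000, 2000.0),          # 40-s record: non-overlapping frames
        (2000, 0.0),              # record equals one frame: all coincide
        (5000, 3000.0 / 9.0),     # fractional shift
    ])
    def test_framing_equation(self, s_l, expected):
        assert frame_shift(s_l, 2000, 10) == pytest.approx(expected)

    def test_frame_count_below_two_rejected(self):
        with pytest.raises(ValueError, match="F_n - 1"):
            frame_shift(5000, 2000, 1)


class TestFrameBlock:
    def test_40s_record_exact_tiling(self):
        """20,000 samples with defaults: 10 frames of 2,000, no overlap."""
        rec = make_record(20000)
        blk = frame_block(rec)
        assert blk.shape == (10, 2000, 12)
        np.testing.assert_array_equal(blk.offsets, np.arange(10) * 2000)
        assert blk.overlap == pytest.approx(0.0)
        assert blk.nominal_shift == pytest.approx(2000.0)

    def test_short_record_overlapping_frames(self):
        """5,000 samples: frames overlap by about 1,667 samples."""
        rec = make_record(5000)
        blk = frame_block(rec)
        assert blk.shape == (10, 2000, 12)
        assert blk.offsets[0] == 0 and blk.offsets[-1] == 3000
        expected = np.rint(np.arange(10) * 3000.0 / 9.0).astype(int)
        np.testing.assert_array_equal(blk.offsets, expected)
        overlaps = [2000 - (blk.offsets[i + 1] - blk.offsets[i]) for i in range(9)]
        assert all(abs(o - 5000 / 3) <= 1.0 for o in overlaps)

    def test_record_shorter_than_frame_is_padded_and_replicated(self):
        rec = make_record(1500)
        blk = frame_block(rec, FrameConfig(pad_value=0.0))
        assert blk.shape == (10, 2000, 12)
        np.testing.assert_array_equal(blk.offsets, 0)
        padded = np.vstack([rec.signal, np.zeros((500, 12))])
        for i in range(10):
            np.testing.assert_array_equal(blk.data[i], padded)

    def test_frames_are_contiguous_slices(self, rng):
        """Slice fidelity against a brute-force slicer on random records."""
        for _ in range(20):
            s_l = int(rng.integers(500, 8000))
            rec = make_record(s_l, n_leads=3, seed=int(rng.integers(10000)))
            cfg = FrameConfig(frame_length=400, frame_count=6)
            blk = frame_block(rec, cfg)
            src = rec.signal
            if s_l < 400:
                src = np.vstack([src, np.zeros((400 - s_l, 3))])
            for i, o in enumerate(blk.offsets):
                np.testing.assert_array_equal(blk.data[i], src[o:o + 400])

    @given(s_l=st.integers(min_value=2000, max_value=40000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_coverage_anchors(self, s_l):
        """First frame starts at 0; last frame ends exactly at S_l."""
        offsets = frame_offsets(s_l, FrameConfig())
        assert offsets[0] == 0
        assert offsets[-1] + 2000 == s_l

    @pytest.mark.parametrize("s_l", [2000, 3000, 5000, 19999, 20000, 27001])
    def test_emitted_block_satisfies_overlap_identity(self, s_l):
        """f_o = F_l - F_s holds exactly on every emitted FrameBlock."""
        blk = frame_block(make_record(s_l, n_leads=2))
        assert blk.overlap == 2000 - blk.nominal_shift

    @given(s_l=st.integers(min_value=2001, max_value=20000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_union_of_frames_covers_record_when_shift_small(self, s_l):
        """For F_s <= F_l every sample index lands in some frame."""
        offsets = frame_offsets(s_l, FrameConfig())
        covered = np.zeros(s_l, dtype=bool)
        for o in offsets:
            covered[o:o + 2000] = True
        assert covered.all()

    def test_determinism(self):
        rec = make_record(7000)
        a, b = frame_block(rec), frame_block(rec)
        np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(a.offsets, b.offsets)

    def test_long_record_gaps_allowed(self):
        """Records beyond F_n * F_l samples: frames sample uniformly with gaps."""
        rec = make_record(30000)
        blk = frame_block(rec)
        assert blk.nominal_shift > 2000
        assert blk.overlap < 0
        assert blk.offsets[-1] + 2000 == 30000


class TestPadOrTruncate:
    def test_short_record_zero_padded(self):
        rec = make_record(12500)  # 25 s at 500 Hz
        out = pad_or_truncate(rec)
        assert out.n_samples == 20000
        np.testing.assert_array_equal(out.signal[:12500], rec.signal)
        np.testing.assert_array_equal(out.signal[12500:], 0.0)

    def test_long_record_truncated_to_prefix(self):
        rec = make_record(30000)  # 60 s
        out = pad_or_truncate(rec)
        assert out.n_samples == 20000
        np.testing.assert_array_equal(out.signal, rec.signal[:20000])

    def test_exact_length_is_fixed_point(self):
        rec = make_record(20000)
        assert pad_or_truncate(rec) is rec

    def test_baseline_block_matches_frame_block_of_padded_record(self):
        rec = make_record(12500)
        blk = block_from_fixed_length(rec)
        assert blk.shape == (10, 2000, 12)
        assert blk.overlap == pytest.approx(0.0)
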