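"""Region tracking, noise-subspace projection, band-pass, gradient clip."""

import numpy as np
import pytest
from scipy import signal as sps

from ratresp import (MaskSequence, NoiseRegressorSet, TimeSeries,
                     area_signal, bandpass_respiration, build_noise_subspace,
                     clip_gradient, denoise_projection, fill_gaps,
                     track_region)
from ratresp.signal_extraction import align_to_com, standardize


def _seq_from_masks(mask_list, fps=60.0, scores=None):
    masks = np.stack(mask_list)
    scores = np.ones(len(masks)) if scores is None else scores
    return MaskSequence(masks, scores, fps)


class TestTrackRegion:
    def test_single_pixel(self):
        m = np.zeros((10, 10), bool)
        m[3, 7] = True
        tr = track_region(_seq_from_masks([m]))
        assert tr.area[0] == 1
        assert (tr.com_y[0], tr.com_x[0]) == (3, 7)
        assert tuple(tr.bbox[0]) == (3, 7, 4, 8)

    def test_square_symmetry(self):
        m = np.zeros((10, 10), bool)
        m[2:6, 2:6] = True
        tr = track_region(_seq_from_masks([m]))
        assert tr.area[0] == 16
        assert tr.com_y[0] == pytest.approx(3.5)
        assert tr.com_x[0] == pytest.approx(3.5)

    def test_l_shape_three_point_average(self):
        m = np.zeros((5, 5), bool)
        m[0, 0] = m[1, 0] = m[1, 1] = True
        tr = track_region(_seq_from_masks([m]))
        assert tr.area[0] == 3
        assert tr.com_y[0] == pytest.approx(2 / 3)
        assert tr.com_x[0] == pytest.approx(1 / 3)

    def test_all_invalid_raises(self):
        m = np.zeros((5, 5), bool)
        with pytest.raises(ValueError):
            track_region(_seq_from_masks([m, m]))


def _square_seq(areas, valid=None, fps=60.0):
    """One centered square per frame with the requested pixel count."""
    masks = []
    for a in areas:
        m = np.zeros((40, 40), bool)
        side = max(1, int(round(np.sqrt(a))))
        m[10:10 + side, 10:10 + side] = a > 0
        masks.append(m)
    scores = np.ones(len(masks)) if valid is None \
        else np.where(valid, 1.0, 0.0)
    return _seq_from_masks(masks, fps, scores)


class TestFillGaps:
    def _track(self, areas, valid):
        seq = _square_seq([100] * len(areas))
        tr = track_region(seq)
        tr.area = np.asarray(areas, float)
        tr.valid = np.asarray(valid, bool)
        tr.area[~tr.valid] = 0.0
        tr.com_x[~tr.valid] = np.nan
        tr.com_y[~tr.valid] = np.nan
        return tr

    def test_single_gap_linear_midpoint(self):
        tr = self._track([100, 0, 102], [True, False, True])
        (seg,) = fill_gaps(tr, max_gap_s=0.5)
        assert seg.area.tolist() == [100, 101, 102]

    def test_no_gaps_identity(self):
        tr = self._track([100, 101, 102], [True] * 3)
        (seg,) = fill_gaps(tr, max_gap_s=0.5)
        assert seg.area.tolist() == [100, 101, 102]

    def test_long_gap_splits_with_exact_bookkeeping(self):
        n, gap = 200, 60  # 1 s gap at 60 fps > max_gap 0.5 s
        valid = np.ones(n, bool)
        valid[80:80 + gap] = False
        tr = self._track(np.where(valid, 100.0, 0.0), valid)
        segs = fill_gaps(tr, max_gap_s=0.5)
        assert len(segs) == 2
        assert len(segs[0]) + len(segs[1]) + gap == n


class TestNoiseSubspace:
    def _track_with_com(self, com_x, com_y):
        n = len(com_x)
        seq = _square_seq([100] * n)
        tr = track_region(seq)
        tr.com_x = np.asarray(com_x, float)
        tr.com_y = np.asarray(com_y, float)
        return tr

    def test_linear_com_detrends_to_zero(self):
        t = np.arange(100, dtype=float)
        q = build_noise_subspace(self._track_with_com(3 * t + 7, 0 * t + 5))
        assert np.abs(q.columns[:, 0]).max() < 1e-9   # detrended x
        assert np.abs(q.columns[:, 1]).max() < 1e-9   # constant y

    def test_constant_com_gives_all_zero_columns(self):
        q = build_noise_subspace(self._track_with_com([5.0] * 50, [7.0] * 50))
        assert np.abs(q.columns).max() < 1e-9

    def test_derivative_column_keeps_drift_frequency(self):
        fs, f0 = 60.0, 0.7
        t = np.arange(600) / fs
        q = build_noise_subspace(
            self._track_with_com(5 * np.sin(2 * np.pi * f0 * t),
                                 np.zeros(600)))
        f, p = sps.periodogram(q.columns[:, 2], fs=fs)
        assert abs(f[np.argmax(p)] - f0) <= f[1] - f[0]

    def test_too_few_frames_raise(self):
        with pytest.raises(ValueError):
            build_noise_subspace(self._track_with_com([1, 2], [1, 2]))

    def test_all_columns_have_zero_fit_line(self):
        rngv = np.random.default_rng(1)
        tr = self._track_with_com(rngv.normal(size=300),
                                  rngv.normal(size=300))
        q = build_noise_subspace(tr)
        t = np.arange(300)
        for j in range(4):
            slope, intercept = np.polyfit(t, q.columns[:, j], 1)
            assert abs(slope) < 1e-10 and abs(intercept) < 1e-8


class TestDenoiseProjection:
    def test_zero_subspace_is_identity(self):
        R = TimeSeries(np.sin(np.arange(100) / 5), 60.0)
        Q = NoiseRegressorSet(np.zeros((100, 4)))
        Z = denoise_projection(R, Q)
        np.testing.assert_allclose(Z.values, R.values)

    def test_signal_inside_subspace_vanishes(self, rng):
        q = rng.normal(size=(200, 4))
        R = TimeSeries(q[:, 2].copy(), 60.0)
        Z = denoise_projection(R, NoiseRegressorSet(q))
        assert np.abs(Z.values).max() < 1e-8 * np.abs(R.values).max()

    def test_orthogonality_oracle(self, rng):
        r = rng.normal(size=600)
        q = rng.normal(size=(600, 4))
        Z = denoise_projection(TimeSeries(r, 60.0), NoiseRegressorSet(q))
        resid = np.abs(q.T @ Z.values).max()
        assert resid < 1e-8 * np.linalg.norm(q) * np.linalg.norm(r)

    def test_projection_is_idempotent(self, rng):
        r = rng.normal(size=300)
        q = rng.normal(size=(300, 4))
        Q = NoiseRegressorSet(q)
        Z1 = denoise_projection(TimeSeries(r, 60.0), Q)
        Z2 = denoise_projection(Z1, Q)
        np.testing.assert_allclose(Z2.values, Z1.values, atol=1e-10)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            denoise_projection(TimeSeries(np.zeros(10), 60.0),
                               NoiseRegressorSet(np.zeros((9, 2))))

    def test_rank_deficient_subspace_tolerated(self, rng):
        col = rng.normal(size=300)
        q = np.column_stack([col, col, np.zeros(300), 2 * col])
        r = rng.normal(size=300)
        Z = denoise_projection(TimeSeries(r, 60.0), NoiseRegressorSet(q))
        assert np.abs(q.T @ Z.values).max() < 1e-8 * np.linalg.norm(r) \
            * np.linalg.norm(q)


class TestBandpass:
    def test_dc_rejection(self):
        ts = TimeSeries(np.full(600, 7.0), 60.0)
        out = bandpass_respiration(ts)
        assert np.abs(out.values).max() < 1e-6 * 7.0

    def _steady_amplitude(self, f, fs=60.0, dur=60.0):
        t = np.arange(int(dur * fs)) / fs
        out = bandpass_respiration(TimeSeries(np.sin(2 * np.pi * f * t), fs))
        mid = out.values[len(out) // 4: -len(out) // 4]
        return np.abs(mid).max()

    def _analytic_gain(self, f, fs=60.0):
        sos = sps.butter(2, [1.0, 3.3], btype="bandpass", fs=fs,
                         output="sos")
        _, h = sps.sosfreqz(sos, worN=[f], fs=fs)
        return np.abs(h[0]) ** 2   # forward-backward squares the response

    def test_passband_tone_preserved(self):
        amp = self._steady_amplitude(1.6)
        assert 0.9 <= amp <= 1.1
        assert amp == pytest.approx(self._analytic_gain(1.6), abs=0.02)

    def test_stopband_tone_suppressed(self):
        amp = self._steady_amplitude(0.2)
        assert amp < 0.1
        assert amp == pytest.approx(self._analytic_gain(0.2), abs=0.02)

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError):
            bandpass_respiration(TimeSeries(np.zeros(20), 60.0))


class TestClipGradient:
    def test_smooth_signal_is_identity(self):
        t = np.arange(600) / 60.0
        x = np.sin(2 * np.pi * 1.6 * t)  # max slope ~0.17/sample
        out = clip_gradient(TimeSeries(x, 60.0), 1.5)
        np.testing.assert_array_equal(out.values, x)

    def test_spike_removed_by_neighbor_interpolation(self):
        out = clip_gradient(TimeSeries([0, 0, 5, 0, 0], 60.0), 1.5)
        np.testing.assert_allclose(out.values, np.zeros(5))

    def test_steep_ramp_flags_everything(self):
        with pytest.raises(ValueError):
            clip_gradient(TimeSeries(2.0 * np.arange(50), 60.0), 1.5)

    def test_edge_spike_extends_nearest_survivor(self):
        out = clip_gradient(TimeSeries([9.0, 1.0, 1.0, 1.0], 60.0), 1.5)
        np.testing.assert_allclose(out.values, np.ones(4))


class TestComAlignment:
    def test_area_signal_bit_identical_after_alignment(self, blob_default):
        _, seq, _ = blob_default
        track = track_region(seq)
        aligned = align_to_com(seq, track)
        a0 = area_signal(track).values
        a1 = area_signal(track_region(aligned)).values
        assert (a0 == a1).all()


def test_standardize_is_unit_variance():
    ts = standardize(TimeSeries(np.random.default_rng(0).normal(
        5, 3, size=500), 60.0))
    assert abs(ts.values.mean()) < 1e-12
    assert ts.values.std() == pytest.approx(1.0)
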