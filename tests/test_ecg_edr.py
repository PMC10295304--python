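"""R-peak detection, EDR extraction and spectral inspection."""

import numpy as np
import pytest
from scipy import signal as sps

from ratresp import (EcgRecording, EcgSpec, RPeakSet, TimeSeries,
                     detect_r_peaks, dominant_rate, edr_rate, extract_edr,
                     generate_rat_ecg, preprocess_ecg, respiration_spectrum)
from ratresp.ecg_edr import lowpass_edr


def _detected(ecg, **kw):
    return detect_r_peaks(preprocess_ecg(EcgRecording(ecg)), **kw)


class TestPreprocess:
    def test_powerline_tone_suppressed(self):
        fs = 500.0
        t = np.arange(int(10 * fs)) / fs
        rec = EcgRecording(TimeSeries(np.sin(2 * np.pi * 50 * t), fs))
        out = preprocess_ecg(rec)
        mid = out.signal.values[500:-500]
        assert np.abs(mid).max() < 0.05

    def test_respiratory_band_survives_edr_lowpass(self):
        fs = 100.0
        t = np.arange(int(30 * fs)) / fs
        x = 2.0 + np.sin(2 * np.pi * 1.5 * t)
        out = lowpass_edr(TimeSeries(x, fs), 4.0)
        mid = out.values[300:-300]
        # DC passes, the 1.5 Hz tone keeps its amplitude within 5%
        assert np.abs(mid - 2.0).max() == pytest.approx(1.0, rel=0.05)

    def test_zero_signal_stays_zero(self):
        rec = EcgRecording(TimeSeries(np.zeros(5000), 500.0))
        out = preprocess_ecg(rec)
        np.testing.assert_allclose(out.signal.values, 0.0, atol=1e-12)

    def test_low_rate_skips_notch_with_warning(self):
        rec = EcgRecording(TimeSeries(np.ones(100), 80.0))
        with pytest.warns(UserWarning, match="notch skipped"):
            out = preprocess_ecg(rec)
        np.testing.assert_allclose(out.signal.values, 1.0)


class TestDetectRPeaks:
    def test_clean_synthetic_ecg_full_recall(self, ecg_default):
        spec, ecg, truth = ecg_default
        peaks = _detected(ecg)
        assert abs(len(peaks) - 360) <= 1
        # every detected peak within one sample of a truth pulse center
        d = np.abs(peaks.indices[:, None] - truth.r_indices[None, :])
        assert d.min(axis=1).max() <= 1

    def test_constant_signal_yields_empty(self):
        peaks = detect_r_peaks(EcgRecording(TimeSeries(np.ones(5000),
                                                       500.0)))
        assert len(peaks) == 0

    def test_close_pulse_pair_merged_by_min_delay(self):
        fs = 500.0
        t = np.arange(int(2 * fs)) / fs
        x = np.zeros_like(t)
        for tc, amp in ((1.0, 1.0), (1.05, 0.8)):  # 0.05 s apart
            x += amp * np.exp(-0.5 * ((t - tc) / 0.008) ** 2)
        peaks = detect_r_peaks(EcgRecording(TimeSeries(x, fs)),
                               min_delay=0.1)
        assert len(peaks) == 1
        assert abs(peaks.indices[0] - 500) <= 1  # the larger pulse wins

    def test_spacing_respects_min_delay(self, ecg_default):
        _, ecg, _ = ecg_default
        peaks = _detected(ecg, min_delay=0.1)
        assert np.diff(peaks.indices).min() >= 0.1 * 500

    def test_recall_survives_heavy_noise(self):
        # about 10 dB SNR on the QRS peaks
        spec = EcgSpec(duration_s=60.0, noise_sd=0.1, seed=11)
        ecg, truth = generate_rat_ecg(spec)
        peaks = _detected(ecg)
        d = np.abs(peaks.times[:, None] - truth.r_times[None, :])
        recall = (d.min(axis=0) < 0.02).mean()
        assert recall >= 0.99


class TestExtractEdr:
    def test_unmodulated_ecg_gives_near_zero_edr(self):
        base = dict(duration_s=60.0, noise_sd=0.0, powerline_amp=0.0,
                    seed=2)
        ecg_mod, _ = generate_rat_ecg(EcgSpec(am_depth=0.3, **base))
        ecg_flat, _ = generate_rat_ecg(EcgSpec(am_depth=0.0, **base))
        edr_mod = extract_edr(_detected(ecg_mod))
        edr_flat = extract_edr(_detected(ecg_flat))
        rms = lambda v: np.sqrt(np.mean(v ** 2))  # noqa: E731
        assert rms(edr_flat.values) < 0.05 * rms(edr_mod.values)

    def test_edr_dominant_frequency_matches_rr(self):
        ecg, _ = generate_rat_ecg(EcgSpec(duration_s=60.0, rr_true=100.0,
                                          seed=4))
        edr = extract_edr(_detected(ecg))
        f, p = sps.periodogram(edr.values, fs=edr.rate_hz)
        assert abs(f[np.argmax(p)] - 100 / 60) <= f[1] - f[0]

    def test_uniform_identical_amplitudes_give_zero(self):
        idx = np.arange(20) * 50
        peaks = RPeakSet(idx, np.ones(20), 500.0)
        edr = extract_edr(peaks)
        assert np.abs(edr.values).max() < 1e-9

    def test_slow_beat_rate_raises_undersampled(self):
        idx = np.arange(10) * 250   # 2 beats/s
        peaks = RPeakSet(idx, np.ones(10) + 0.1 * np.arange(10), 500.0)
        with pytest.raises(ValueError, match="undersampled"):
            extract_edr(peaks, band_low_hz=1.0, band_high_hz=3.3)

    def test_too_few_peaks_raise(self):
        with pytest.raises(ValueError):
            extract_edr(RPeakSet(np.array([0, 100]), np.ones(2), 500.0))

    def test_modulation_depth_scales_edr_linearly(self):
        base = dict(duration_s=60.0, noise_sd=0.0, powerline_amp=0.0,
                    seed=6)
        rms = []
        for depth in (0.1, 0.2):
            ecg, _ = generate_rat_ecg(EcgSpec(am_depth=depth, **base))
            edr = extract_edr(_detected(ecg))
            rms.append(np.sqrt(np.mean(edr.values ** 2)))
        assert rms[1] / rms[0] == pytest.approx(2.0, rel=0.1)


class TestEdrRate:
    def test_recovers_true_rate(self, ecg_default):
        _, ecg, truth = ecg_default
        edr = extract_edr(_detected(ecg))
        rr = edr_rate(edr)
        assert 94.0 <= rr.mean_rr <= 98.0

    def test_empty_edr_gives_empty_series(self):
        rr = edr_rate(TimeSeries(np.empty(0), 20.0))
        assert rr.is_empty and np.isnan(rr.mean_rr)

    def test_spectrum_shows_fundamental_and_first_harmonic(self):
        ecg, _ = generate_rat_ecg(EcgSpec(duration_s=120.0, rr_true=100.0,
                                          am_depth=0.4, seed=8))
        edr = extract_edr(_detected(ecg))
        freq, power = respiration_spectrum(edr)
        fund = freq[np.argmax(power)]
        assert abs(fund - 100.0) <= freq[1] - freq[0]
        # energy concentrates near the fundamental and its first harmonic
        near = lambda f0: power[np.abs(freq - f0) < 10].max()  # noqa: E731
        floor = np.median(power)
        assert near(100.0) > 3 * floor
        assert near(200.0) > floor


class TestRespirationSpectrum:
    def test_pure_tone_peaks_at_100_bpm(self):
        fs = 20.0
        t = np.arange(int(60 * fs)) / fs
        freq, power = respiration_spectrum(
            TimeSeries(np.sin(2 * np.pi * 1.667 * t), fs))
        binw = freq[1] - freq[0]
        assert abs(freq[np.argmax(power)] - 100.0) <= binw
        assert dominant_rate(freq, power) is not None

    def test_white_noise_has_no_dominant_rate(self, rng):
        freq, power = respiration_spectrum(
            TimeSeries(rng.normal(size=1200), 20.0))
        assert dominant_rate(freq, power) is None

    def test_weak_harmonic_does_not_displace_fundamental(self):
        fs = 20.0
        t = np.arange(int(60 * fs)) / fs
        x = np.sin(2 * np.pi * 1.6 * t) + 0.3 * np.sin(2 * np.pi * 3.2 * t)
        freq, power = respiration_spectrum(TimeSeries(x, fs))
        binw = freq[1] - freq[0]
        assert abs(freq[np.argmax(power)] - 96.0) <= binw
        k2 = np.abs(freq - 192.0) < 2 * binw
        assert power[k2].max() > 3 * np.median(power)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            respiration_spectrum(TimeSeries(np.zeros(50), 20.0))


def test_hr_and_rr_bands_never_confused(ecg_default):
    """EDR spectrum peaks at the respiratory, never the cardiac, rate."""
    _, ecg, truth = ecg_default
    edr = extract_edr(_detected(ecg))
    freq, power = respiration_spectrum(edr)
    peak_bpm = freq[np.argmax(power)]
    assert abs(peak_bpm - truth.rr_true) < abs(peak_bpm - truth.hr_bpm)
    assert peak_bpm < 210.0
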