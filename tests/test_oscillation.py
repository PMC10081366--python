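"""Bandpass, correlation and power-spectrum oscillation analysis."""

import numpy as np
import pytest

from serovolt import oscillation, synthetic
from serovolt.datatypes import FSCAVSeries, ValidationError


def tone_series(period_min, n=240, amplitude=5.0, baseline=60.0, phase=0.0):
    t = np.arange(n, dtype=float)  # one sample per minute
    x = baseline + amplitude * np.sin(2 * np.pi * t / period_min + phase)
    return FSCAVSeries(t, x)


class TestBandpass:
    def test_dc_rejection(self):
        series = FSCAVSeries(np.arange(120.0), np.full(120, 55.0))
        out = oscillation.bandpass(series)
        assert abs(out.concentration_nM.mean()) < 1e-6 * 55.0
        assert np.abs(out.concentration_nM).max() < 1e-6 * 55.0

    def test_in_band_tone_preserved(self):
        series = tone_series(8.0)  # 0.00208 Hz, mid-band
        out = oscillation.bandpass(series)
        gain = out.concentration_nM.std() / (5.0 / np.sqrt(2.0))
        assert gain == pytest.approx(1.0, abs=0.10)

    def test_stopband_tone_attenuated(self):
        series = tone_series(2.5)  # 0.0067 Hz, above the 0.005 Hz cutoff
        out = oscillation.bandpass(series)
        gain = out.concentration_nM.std() / (5.0 / np.sqrt(2.0))
        assert gain < 0.1

    def test_short_series_warns(self):
        series = tone_series(8.0, n=30)
        with pytest.warns(UserWarning):
            oscillation.bandpass(series)

    def test_non_uniform_sampling_rejected(self):
        t = np.array([0.0, 1.0, 3.0, 4.0, 5.0, 6.0])
        with pytest.raises(ValidationError):
            oscillation.bandpass(FSCAVSeries(t, np.ones(6)))


class TestAutocorrelation:
    def test_lag_zero_is_exactly_one(self):
        rng = np.random.default_rng(0)
        series = FSCAVSeries(np.arange(100.0), rng.normal(size=100))
        r = oscillation.autocorrelation(series, 10)
        assert r[0] == 1.0

    def test_bounded_by_one(self):
        rng = np.random.default_rng(1)
        for seed in range(5):
            x = np.random.default_rng(seed).normal(size=150).cumsum()
            series = FSCAVSeries(np.arange(150.0), x)
            r = oscillation.autocorrelation(series, 60)
            assert np.all(np.abs(r) <= 1.0 + 1e-12)

    def test_sinusoid_peak_at_one_period(self):
        series = tone_series(8.0, n=240, baseline=0.0)
        r = oscillation.autocorrelation(series, 16)
        assert r[8] >= 0.95

    def test_white_noise_within_sampling_bound(self):
        n = 400
        x = np.random.default_rng(42).normal(size=n)
        series = FSCAVSeries(np.arange(float(n)), x)
        r = oscillation.autocorrelation(series, 10)
        assert np.all(np.abs(r[1:]) < 3.0 / np.sqrt(n))

    def test_zero_variance_rejected(self):
        series = FSCAVSeries(np.arange(50.0), np.full(50, 2.0))
        with pytest.raises(ValidationError):
            oscillation.autocorrelation(series, 5)


class TestSlidingWindowCorrelation:
    def test_periodic_series_column_is_one_at_period_lag(self):
        series = tone_series(8.0, n=120, baseline=0.0)
        mat = oscillation.sliding_window_correlation(series, lags=[8],
                                                     window_min=24.0)
        assert np.allclose(mat, 1.0, atol=1e-9)

    def test_antiphase_at_half_period(self):
        series = tone_series(8.0, n=120, baseline=0.0)
        mat = oscillation.sliding_window_correlation(series, lags=[4],
                                                     window_min=24.0)
        assert np.allclose(mat, -1.0, atol=1e-9)

    def test_shape_contract(self):
        series = tone_series(8.0, n=120)
        lags = [0, 2, 4, 6]
        mat = oscillation.sliding_window_correlation(series, lags=lags,
                                                     window_min=25.0)
        n_starts = 120 - 25 + 1 - max(lags)
        assert mat.shape == (n_starts, len(lags))

    def test_zero_variance_window_marked_nan(self):
        x = np.zeros(80)
        x[60:] = np.sin(np.arange(20))
        series = FSCAVSeries(np.arange(80.0), x)
        mat = oscillation.sliding_window_correlation(series, lags=[1],
                                                     window_min=25.0)
        assert np.isnan(mat[0, 0])

    def test_window_beyond_span_rejected(self):
        series = tone_series(8.0, n=20)
        with pytest.raises(ValidationError):
            oscillation.sliding_window_correlation(series, lags=[10],
                                                   window_min=25.0)


class TestWelchPSD:
    def test_tone_lands_on_nearest_bin(self):
        # 128-min series puts the 8-min tone (1/480 Hz) exactly on a bin
        spec = synthetic.SyntheticBasalSpec(
            oscillation_period_min=8.0, noise_sd_nM=0.0, duration_min=128.0)
        series = synthetic.simulate_basal_series(spec)
        psd = oscillation.welch_psd(series)
        f_peak = psd.frequencies_hz[np.argmax(psd.power)]
        assert f_peak == pytest.approx(1.0 / 480.0, rel=1e-9)

    def test_normalization_sums_to_one(self):
        series = tone_series(8.0, n=120)
        psd = oscillation.welch_psd(series)
        assert psd.normalized_power.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(psd.normalized_power >= 0)

    def test_white_noise_spectrum_roughly_flat(self):
        acc = None
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=256)
            psd = oscillation.welch_psd(FSCAVSeries(np.arange(256.0), x))
            acc = psd.normalized_power if acc is None else acc + psd.normalized_power
        acc = acc / 20.0
        inner = acc[1:-1]  # edge bins carry half-width
        assert inner.max() / inner.min() < 5.0

    def test_too_short_series_rejected(self):
        with pytest.raises(ValidationError):
            oscillation.welch_psd(FSCAVSeries(np.arange(2.0), np.ones(2)))


class TestWeightedFrequency:
    def test_tone_wf_close_to_tone_frequency(self):
        spec = synthetic.SyntheticBasalSpec(
            oscillation_period_min=8.0, noise_sd_nM=0.0, duration_min=128.0)
        series = oscillation.bandpass(synthetic.simulate_basal_series(spec))
        psd = oscillation.welch_psd(series)
        bin_width = psd.frequencies_hz[1] - psd.frequencies_hz[0]
        assert abs(psd.weighted_frequency_hz - 1.0 / 480.0) < bin_width

    def test_equal_power_two_bins_gives_midpoint(self):
        freqs = np.array([0.001, 0.002, 0.003, 0.004])
        power = np.array([0.0, 1.0, 0.0, 1.0])
        psd = oscillation.PSDResult(freqs, power, power / power.sum(), 0.0)
        assert oscillation.weighted_frequency(psd) == pytest.approx(0.003)

    def test_shifting_mass_upward_increases_wf(self):
        freqs = np.linspace(0.001, 0.005, 9)
        low = np.exp(-np.arange(9.0))
        high = low[::-1]
        wf_low = oscillation.weighted_frequency(
            oscillation.PSDResult(freqs, low, low / low.sum(), 0.0))
        wf_high = oscillation.weighted_frequency(
            oscillation.PSDResult(freqs, high, high / high.sum(), 0.0))
        assert wf_high > wf_low

    def test_wf_inside_frequency_grid(self):
        for seed in range(5):
            x = np.random.default_rng(seed).normal(size=128)
            psd = oscillation.welch_psd(FSCAVSeries(np.arange(128.0), x))
            wf = oscillation.weighted_frequency(psd)
            assert psd.frequencies_hz[0] <= wf <= psd.frequencies_hz[-1]

    def test_all_zero_power_rejected(self):
        psd = oscillation.PSDResult(np.array([0.1, 0.2]), np.zeros(2),
                                    np.zeros(2), 0.0)
        with pytest.raises(ValidationError):
            oscillation.weighted_frequency(psd)


def basal(period, seed, duration=60.0):
    spec = synthetic.SyntheticBasalSpec(
        oscillation_period_min=period, oscillation_amplitude_nM=5.0,
        noise_sd_nM=1.0, ar1_coefficient=0.3, duration_min=duration,
        seed=seed)
    return synthetic.simulate_basal_series(spec)


class TestComparePrePost:
    def test_identical_series_give_zero_delta(self):
        pre = [basal(8.0, s) for s in range(3)]
        table, summary = oscillation.compare_pre_post(pre, pre)
        assert np.allclose(table.delta_hz, 0.0)
        assert summary["direction"] == "no-change"

    def test_faster_post_oscillation_gives_positive_shift(self):
        pre = [basal(10.0, s) for s in range(5)]
        post = [basal(6.0, 100 + s) for s in range(5)]
        table, summary = oscillation.compare_pre_post(pre, post)
        assert np.all(table.delta_hz > 0)
        assert summary["direction"] == "uptake1-like"

    def test_slower_post_oscillation_gives_negative_shift(self):
        pre = [basal(6.0, s) for s in range(5)]
        post = [basal(10.0, 100 + s) for s in range(5)]
        table, summary = oscillation.compare_pre_post(pre, post)
        assert np.all(table.delta_hz < 0)
        assert summary["direction"] == "uptake2-like"

    def test_unmatched_lists_rejected(self):
        with pytest.raises(ValidationError):
            oscillation.compare_pre_post([basal(8.0, 0)], [])
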