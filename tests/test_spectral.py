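import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oscana import spectral
from oscana.spectral import (
    band_power,
    band_summary,
    coherence,
    coherence_confidence_limit,
    segment_spectra,
    standardize,
    wavelet_power,
)


def periodogram_average_oracle(x, L, fs):
    """Independent direct-DFT oracle: mean over disjoint segments of the
    boxcar periodogram, computed with an explicit loop and explicit DFT."""
    m = len(x) // L
    freqs = np.fft.rfftfreq(L, 1 / fs)
    acc = np.zeros(freqs.size)
    n = np.arange(L)
    for seg in range(m):
        s = x[seg * L : (seg + 1) * L]
        for ki, k in enumerate(range(freqs.size)):
            coef = np.sum(s * np.exp(-2j * np.pi * k * n / L))
            acc[ki] += np.abs(coef) ** 2 / (fs * L)
    acc /= m
    dbl = np.full(freqs.size, 2.0)
    dbl[0] = 1.0
    if L % 2 == 0:
        dbl[-1] = 1.0
    return freqs, acc * dbl


class TestStandardize:
    def test_constant_errors(self):
        with pytest.raises(ValueError, match="constant|variance"):
            standardize(np.full(10, 3.0))

    def test_moments(self, rng):
        z = standardize(rng.standard_normal(100) * 7 + 3)
        assert abs(z.mean()) < 1e-12
        assert abs(z.std() - 1.0) < 1e-12

    def test_idempotent(self, rng):
        z = standardize(rng.standard_normal(50))
        np.testing.assert_allclose(standardize(z), z, atol=1e-12)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_property_moments(self, values):
        x = np.asarray(values)
        if x.std() == 0:
            with pytest.raises(ValueError):
                standardize(x)
        else:
            z = standardize(x)
            assert abs(z.mean()) < 1e-9
            assert abs(z.std() - 1.0) < 1e-9


class TestSegmentSpectra:
    def test_autospectrum_when_x_equals_y(self, rng):
        x = rng.standard_normal(1000)
        est = segment_spectra(x, x, 100, fs=100.0)
        np.testing.assert_allclose(est.Sxy.real, est.Sxx, rtol=1e-10)
        np.testing.assert_allclose(est.Sxy.imag, 0.0, atol=1e-12)

    def test_sinusoid_concentration(self):
        fs, f0, L = 100.0, 10.0, 200  # L covers 20 full periods
        t = np.arange(2000) / fs
        x = np.sin(2 * np.pi * f0 * t)
        est = segment_spectra(x, x, L, fs=fs, taper="boxcar")
        peak = est.freqs[np.argmax(est.Sxx)]
        assert peak == pytest.approx(f0)
        # energy concentrated: peak bin dominates everything else
        others = est.Sxx[np.abs(est.freqs - f0) > 1.0]
        assert est.Sxx.max() > 1e6 * others.max()

    def test_white_noise_matches_periodogram_oracle(self, rng):
        x = rng.standard_normal(5000)
        L = 100
        est = segment_spectra(x, x, L, fs=50.0, taper="boxcar",
                              pre_standardize=False)
        freqs, oracle = periodogram_average_oracle(x, L, 50.0)
        np.testing.assert_allclose(est.freqs, freqs)
        np.testing.assert_allclose(est.Sxx, oracle, rtol=1e-8, atol=1e-10)
        assert est.M == 50

    def test_m1_equals_plain_periodogram(self, rng):
        x = rng.standard_normal(256)
        est = segment_spectra(x, x, 256, fs=1.0, taper="boxcar",
                              pre_standardize=False)
        assert est.M == 1
        _, oracle = periodogram_average_oracle(x, 256, 1.0)
        np.testing.assert_allclose(est.Sxx, oracle, rtol=1e-8, atol=1e-10)

    def test_remainder_dropped(self, rng):
        x = rng.standard_normal(1050)
        est = segment_spectra(x, x, 100, fs=1.0)
        assert est.M == 10
        assert est.remainder == 50

    def test_too_short(self, rng):
        with pytest.raises(ValueError, match="shorter"):
            segment_spectra(np.zeros(10) + np.arange(10), np.arange(10.0), 20)

    def test_multitaper_runs(self, rng):
        x = rng.standard_normal(1000)
        est = segment_spectra(x, x, 250, fs=100.0, taper="multitaper")
        assert np.all(est.Sxx >= 0)


class TestCoherence:
    def test_identical_signals_coherence_one(self, rng):
        x = rng.standard_normal(2000)
        res = coherence(x, x, 200, fs=100.0)
        np.testing.assert_allclose(res.coherence, 1.0, atol=1e-9)

    def test_additive_noise_closed_form(self, rng):
        # y = x + independent noise at per-frequency SNR s=1 -> coherence 1/2
        n = 12000
        x = rng.standard_normal(n)
        y = x + rng.standard_normal(n)
        res = coherence(x, y, n // 30, fs=200.0)
        mid = res.coherence[2:-2]
        assert mid.mean() == pytest.approx(0.5, abs=0.03)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(1500)
        y = rng.standard_normal(1500) + 0.5 * x
        base = coherence(x, y, 300, fs=1.0)
        scaled = coherence(3.5 * x - 2.0, -0.7 * y + 11.0, 300, fs=1.0)
        np.testing.assert_allclose(scaled.coherence, base.coherence,
                                   atol=1e-9)

    def test_bounded_unit_interval(self, rng):
        for _ in range(5):
            x = rng.standard_normal(600)
            y = rng.standard_normal(600) + rng.uniform(-2, 2) * x
            res = coherence(x, y, 100, fs=1.0)
            assert np.all(res.coherence >= -1e-9)
            assert np.all(res.coherence <= 1.0 + 1e-9)

    def test_single_segment_rejected(self, rng):
        with pytest.raises(ValueError, match="2 segments|M="):
            coherence(rng.standard_normal(100), rng.standard_normal(100), 100)


class TestConfidenceLimit:
    def test_m2_exponent_one(self):
        assert coherence_confidence_limit(2, 0.99) == pytest.approx(0.99)

    def test_m11_value(self):
        # direct evaluation: 1 - 0.01**(1/10)
        assert coherence_confidence_limit(11, 0.99) == pytest.approx(
            1.0 - 0.01 ** 0.1
        )

    def test_strictly_decreasing_to_zero(self):
        ms = [2, 3, 5, 10, 50, 1000, 100000]
        vals = [coherence_confidence_limit(m) for m in ms]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1e-4

    @pytest.mark.parametrize("m,alpha", [(1, 0.99), (0, 0.5)])
    def test_m_below_two_rejected(self, m, alpha):
        with pytest.raises(ValueError, match="M"):
            coherence_confidence_limit(m, alpha)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.5, 1.5])
    def test_bad_alpha(self, alpha):
        with pytest.raises(ValueError, match="alpha"):
            coherence_confidence_limit(5, alpha)

    @given(st.integers(2, 10_000), st.floats(0.01, 0.999))
    @settings(max_examples=100, deadline=None)
    def test_formula_exact(self, m, alpha):
        assert coherence_confidence_limit(m, alpha) == 1.0 - (
            1.0 - alpha
        ) ** (1.0 / (m - 1))

    def test_false_positive_rate_on_independent_noise(self):
        # ~1% of frequencies should exceed the alpha=0.99 limit
        hits = total = 0
        for i in range(60):
            r = np.random.default_rng(4000 + i)
            res = coherence(
                r.standard_normal(2000), r.standard_normal(2000),
                100, fs=100.0, taper="boxcar",
            )
            inner = res.coherence[1:-1]
            hits += int((inner > res.conf_limit).sum())
            total += inner.size
        rate = hits / total
        assert 0.004 < rate < 0.018


class TestWaveletPower:
    def test_pure_sinusoid_peaks_at_frequency(self):
        fs = 250.0
        t = np.arange(int(6 * fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        freqs, power = wavelet_power(x, fs, freqs=np.arange(2.0, 40.0))
        assert freqs[np.argmax(power)] == pytest.approx(10.0)

    def test_two_component_local_maxima(self):
        # amplitude normalization gives a flat frequency response, so the
        # two equal components produce two clear local maxima (3-cycle
        # wavelets are broad: compare against bins well outside the lobe)
        fs = 500.0
        t = np.arange(int(6 * fs)) / fs
        x = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 40 * t)
        freqs, power = wavelet_power(x, fs, freqs=np.arange(5.0, 61.0),
                                     normalization="amplitude")
        i10 = np.argmin(np.abs(freqs - 10))
        i40 = np.argmin(np.abs(freqs - 40))
        trough = np.argmin(np.abs(freqs - 25))
        assert power[i10] > 1.5 * power[trough]
        assert power[i40] > 1.5 * power[trough]
        assert abs(freqs[np.argmax(power[: trough + 1])] - 10) <= 2
        assert abs(freqs[trough + np.argmax(power[trough:])] - 40) <= 2

    def test_zero_signal(self):
        freqs, power = wavelet_power(np.zeros(3000), 250.0,
                                     freqs=np.arange(5.0, 20.0))
        np.testing.assert_allclose(power, 0.0, atol=1e-15)

    def test_too_short_names_minimum(self):
        with pytest.raises(ValueError, match="samples"):
            wavelet_power(np.zeros(100), 250.0, freqs=np.array([1.0]))

    def test_exponent_two_amplitude_calibration(self):
        # amplitude normalization: |W|^2 at the center bin = a^2/2
        fs = 500.0
        a = 3.0
        t = np.arange(int(8 * fs)) / fs
        x = a * np.sin(2 * np.pi * 20.0 * t)
        freqs, power = wavelet_power(
            x, fs, freqs=np.array([20.0]), power_exponent=2,
            normalization="amplitude",
        )
        assert power[0] == pytest.approx(a**2 / 2, rel=0.02)


class TestBandSummary:
    def test_flat_spectrum(self):
        freqs = np.arange(1.0, 101.0)
        summ = band_summary(freqs, np.full(100, 2.5), (30, 100))
        assert summ.mean_value == pytest.approx(2.5)

    def test_single_peak(self):
        freqs = np.arange(1.0, 51.0)
        vals = np.zeros(50)
        vals[9] = 1.0  # 10 Hz
        summ = band_summary(freqs, vals, (4.0, 12.0))
        assert summ.peak_freq == 10.0
        assert summ.peak_value == 1.0

    def test_matches_bruteforce_loop(self, rng):
        freqs = np.linspace(0.5, 120.0, 240)
        vals = rng.random(240)
        lo, hi = 30.0, 100.0
        picked = [v for f, v in zip(freqs, vals) if lo <= f <= hi]
        best = max(
            ((v, f) for f, v in zip(freqs, vals) if lo <= f <= hi)
        )
        summ = band_summary(freqs, vals, (lo, hi))
        assert summ.mean_value == pytest.approx(np.mean(picked))
        assert summ.peak_freq == pytest.approx(best[1])
        assert summ.band == (lo, hi)

    def test_inclusive_edges(self):
        freqs = np.array([4.0, 6.0, 8.0])
        summ = band_summary(freqs, np.array([1.0, 2.0, 3.0]), (4.0, 8.0))
        assert summ.mean_value == pytest.approx(2.0)

    def test_band_outside_range(self):
        with pytest.raises(ValueError, match="outside"):
            band_summary(np.arange(1.0, 50.0), np.ones(49), (30, 100))

    def test_empty_band(self):
        with pytest.raises(ValueError):
            band_summary(np.array([1.0, 10.0]), np.array([1.0, 1.0]),
                         (4.0, 8.0))


class TestBandPower:
    def test_in_band_sinusoid_closed_form(self):
        fs = 500.0
        t = np.arange(int(10 * fs)) / fs
        a = 2.0
        x = a * np.sin(2 * np.pi * 6.0 * t)
        assert band_power(x, fs, (4, 8)) == pytest.approx(a**2 / 2, rel=0.02)

    def test_out_of_band_near_zero(self):
        fs = 500.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * 6.0 * t)
        assert band_power(x, fs, (30, 100)) < 1e-6

    def test_linearity_of_independent_components(self):
        fs = 500.0
        t = np.arange(int(10 * fs)) / fs
        x1 = 1.5 * np.sin(2 * np.pi * 5.0 * t)
        x2 = 0.8 * np.sin(2 * np.pi * 7.0 * t + 1.0)
        p_sum = band_power(x1 + x2, fs, (4, 8))
        assert p_sum == pytest.approx(
            band_power(x1, fs, (4, 8)) + band_power(x2, fs, (4, 8)), rel=0.03
        )

    def test_band_above_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            band_power(np.random.default_rng(0).standard_normal(100), 100.0,
                       (30, 80))
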