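"""Pearson maps and the Morlet CWT / XWT / WTC machinery."""

import numpy as np
import pytest

import veghealth as vh
from veghealth.teleconnection import (FOURIER_FACTOR, dominant_phase,
                                      estimate_ar1)
from conftest import make_cube


def _index(values):
    return vh.ClimateIndexSeries(values=np.asarray(values, float))


class TestPearsonMap:
    def test_perfect_positive_and_negative(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(104)
        v = np.empty((104, 1, 2))
        v[:, 0, 0] = x
        v[:, 0, 1] = -x
        cmap = vh.pearson_map(make_cube(v), _index(x))
        assert cmap.r[0, 0] == pytest.approx(1.0)
        assert cmap.r[0, 1] == pytest.approx(-1.0)
        assert cmap.fraction_positive + cmap.fraction_negative == 100.0

    def test_growing_season_restriction_subsets_pairs(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal((104, 2, 2))
        cmap = vh.pearson_map(make_cube(v), _index(rng.standard_normal(104)),
                              season=(14, 43))
        assert cmap.n_pairs == 2 * 30

    def test_pixels_with_too_few_pairs_masked(self):
        v = np.full((104, 1, 1), 5.0)
        mask = np.zeros_like(v, bool)
        mask[:2] = True
        cmap = vh.pearson_map(make_cube(v, mask=mask),
                              _index(np.arange(104.0)))
        assert np.isnan(cmap.r[0, 0])

    def test_coupled_generator_sign_recovered(self):
        cfg = vh.SyntheticConfig(n_years=8, n_lat=5, n_lon=5,
                                 enso_coupling_bt=2.0, noise_sd_bt=0.5,
                                 rng_seed=2)
        _, bt, enso = vh.generate_fields(cfg)
        cmap = vh.pearson_map(bt, enso)
        assert cmap.fraction_positive >= 95.0

    def test_axis_mismatch_rejected(self):
        with pytest.raises(ValueError):
            vh.pearson_map(make_cube(np.zeros((104, 1, 1))),
                           _index(np.zeros(52)))


class TestCwt:
    def test_sinusoid_peak_at_matching_scale(self):
        n, period = 512, 64.0
        x = np.sin(2 * np.pi * np.arange(n) / period)
        spec = vh.cwt(x)
        power = (np.abs(spec.coefficients) ** 2).mean(axis=1)
        peak_period = spec.periods[power.argmax()]
        step = spec.periods[power.argmax() + 1] / peak_period
        assert period / step <= peak_period <= period * step

    def test_agrees_with_pywt_on_peak_period(self):
        # independent implementation: PyWavelets complex-Morlet transform
        import pywt

        n, period = 512, 64.0
        x = np.sin(2 * np.pi * np.arange(n) / period)
        scales = np.arange(8, 128)
        coeffs, freqs = pywt.cwt(x, scales, "cmor1.5-1.0")
        peak = 1.0 / freqs[(np.abs(coeffs) ** 2).mean(axis=1).argmax()]
        ours = vh.cwt(x)
        mine = ours.periods[(np.abs(ours.coefficients) ** 2)
                            .mean(axis=1).argmax()]
        assert mine == pytest.approx(peak, rel=0.1)

    def test_zero_series_gives_zero_coefficients(self):
        spec = vh.cwt(np.zeros(64), detrend=False, standardize=False)
        assert np.allclose(np.abs(spec.coefficients), 0.0)

    def test_parseval_reconstruction_factor(self):
        # variance ~ dj*dt/(Cdelta*N) * sum |W|^2/s, Cdelta=0.776 (Morlet w0=6)
        # s0 = dt so the ladder reaches the small scales where white
        # noise carries much of its variance
        rng = np.random.default_rng(3)
        x = rng.standard_normal(1024)
        spec = vh.cwt(x, detrend=False, s0=1.0)
        total = (np.abs(spec.coefficients) ** 2
                 / spec.scales[:, None]).sum()
        var_hat = spec.dj * spec.dt / (0.776 * x.size) * total
        assert var_hat == pytest.approx(1.0, rel=0.05)

    def test_nan_input_rejected(self):
        x = np.ones(64)
        x[3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            vh.cwt(x)

    def test_coi_is_symmetric_and_bounded(self):
        spec = vh.cwt(np.random.default_rng(4).standard_normal(128))
        assert np.allclose(spec.coi_scale, spec.coi_scale[::-1])
        assert spec.coi_scale.max() <= spec.scales.max() * 2


class TestXwt:
    def setup_method(self):
        self.n, self.period = 512, 64.0
        t = np.arange(self.n)
        self.x = np.sin(2 * np.pi * t / self.period)
        self.spec_x = vh.cwt(self.x)

    def test_self_cross_phase_is_zero(self):
        res = vh.xwt(self.spec_x, vh.cwt(self.x.copy()))
        strong = res.cross_power > 0.1 * res.cross_power.max()
        assert np.abs(res.phase[strong]).max() < 1e-6

    def test_antiphase_of_negated_series(self):
        res = vh.xwt(self.spec_x, vh.cwt(-self.x))
        strong = res.cross_power > 0.1 * res.cross_power.max()
        assert np.all(np.abs(np.abs(res.phase[strong]) - np.pi) < 1e-6)

    def test_quarter_period_lag_gives_half_pi(self):
        t = np.arange(self.n)
        y = np.sin(2 * np.pi * (t - self.period / 4) / self.period)
        res = vh.xwt(self.spec_x, vh.cwt(y))
        j = np.argmin(np.abs(res.scales - self.period / FOURIER_FACTOR))
        in_coi = res.in_coi()[j]
        assert np.abs(res.phase[j, in_coi].mean()
                      - np.pi / 2) < 0.15

    def test_axis_mismatch_rejected(self):
        with pytest.raises(ValueError):
            vh.xwt(self.spec_x, vh.cwt(np.random.default_rng(0)
                                       .standard_normal(256)))

    def test_surrogate_significance_flags_common_oscillation(self):
        rng = np.random.default_rng(5)
        common = np.sin(2 * np.pi * np.arange(self.n) / self.period)
        x = common + 0.3 * rng.standard_normal(self.n)
        y = common + 0.3 * rng.standard_normal(self.n)
        res = vh.xwt(vh.cwt(x), vh.cwt(y), n_surrogates=60, rng_seed=6)
        j = np.argmin(np.abs(res.scales - self.period / FOURIER_FACTOR))
        assert res.significance[j, res.in_coi()[j]].mean() > 0.9


class TestWtc:
    def test_self_coherence_is_one(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(256)
        res = vh.wtc(x, x.copy(), n_surrogates=0)
        assert np.abs(res.coherence - 1.0).max() < 1e-5

    def test_coherence_bounded_in_unit_interval(self):
        rng = np.random.default_rng(8)
        res = vh.wtc(rng.standard_normal(300), rng.standard_normal(300),
                     n_surrogates=0)
        assert res.coherence.min() >= -1e-9
        assert res.coherence.max() <= 1.0 + 1e-9

    def test_symmetry_under_argument_swap(self):
        rng = np.random.default_rng(9)
        x, y = rng.standard_normal(128), rng.standard_normal(128)
        fwd = vh.wtc(x, y, n_surrogates=0)
        rev = vh.wtc(y, x, n_surrogates=0)
        np.testing.assert_allclose(fwd.coherence, rev.coherence, atol=1e-10)
        np.testing.assert_allclose(fwd.phase, -rev.phase, atol=1e-10)

    def test_band_limited_common_signal(self):
        rng = np.random.default_rng(10)
        n, period = 512, 64.0
        common = np.sin(2 * np.pi * np.arange(n) / period)
        x = common + 0.5 * rng.standard_normal(n)
        y = common + 0.5 * rng.standard_normal(n)
        res = vh.wtc(x, y, n_surrogates=0)

        def band_mean(p):
            j = np.argmin(np.abs(res.scales - p / FOURIER_FACTOR))
            sel = res.in_coi()[j]
            return res.coherence[j, sel].mean()

        assert band_mean(64) > band_mean(16)
        assert band_mean(64) > band_mean(256)

    def test_lengths_must_match(self):
        with pytest.raises(ValueError):
            vh.wtc(np.zeros(64) + np.arange(64), np.arange(128.0))

    def test_significance_mask_present_and_sparse_under_null(self):
        rng = np.random.default_rng(11)
        res = vh.wtc(rng.standard_normal(256), rng.standard_normal(256),
                     n_surrogates=100, rng_seed=12)
        frac = res.significance[res.in_coi()].mean()
        assert 0.0 <= frac < 0.2

    def test_dominant_phase_of_anticorrelated_signals(self):
        rng = np.random.default_rng(13)
        n = 512
        common = np.sin(2 * np.pi * np.arange(n) / 64.0)
        x = common + 0.2 * rng.standard_normal(n)
        y = -common + 0.2 * rng.standard_normal(n)
        res = vh.wtc(x, y, n_surrogates=0)
        assert abs(dominant_phase(res)) > np.pi / 2


class TestAr1Helpers:
    def test_estimate_matches_known_coefficient(self):
        from veghealth.teleconnection import _ar1_surrogate
        rng = np.random.default_rng(14)
        x = _ar1_surrogate(rng, 20000, 0.7)
        assert estimate_ar1(x) == pytest.approx(0.7, abs=0.03)

    def test_estimate_stays_stationary_on_adversarial_input(self):
        # a pure ramp is maximally persistent; the estimate must still be
        # a usable stationary coefficient
        assert estimate_ar1(np.arange(1000.0)) < 1.0
        assert estimate_ar1(np.full(100, 2.5)) == 0.0
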