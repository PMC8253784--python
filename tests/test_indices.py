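"""Smoother, climatology extrema and the VCI/TCI/VHI formulas."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import veghealth as vh
from conftest import make_cube


def _series_cube(series, tag="NDVI"):
    return make_cube(np.asarray(series, float)[:, None, None], tag=tag)


class TestSmoother:
    def test_constant_series_preserved(self):
        out = vh.smooth_series(_series_cube(np.full(52, 0.3)))
        np.testing.assert_allclose(out.values[:, 0, 0], 0.3, atol=1e-12)
        assert out.tag == "SMN"

    def test_isolated_spike_removed_by_median(self):
        s = np.zeros(52)
        s[20] = 5.0
        out = vh.smooth_series(_series_cube(s), window_weeks=5)
        assert abs(out.values[20, 0, 0]) < 1e-12

    def test_linear_ramp_unchanged_in_interior(self):
        # symmetric triangular weights reproduce linear signals exactly
        ramp = np.linspace(0.0, 0.51, 52)
        out = vh.smooth_series(_series_cube(ramp), window_weeks=5)
        np.testing.assert_allclose(out.values[2:-2, 0, 0], ramp[2:-2],
                                   atol=1e-12)

    def test_hand_applied_kernel_matches(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=52)
        out = vh.smooth_series(_series_cube(s), window_weeks=5)
        # oracle: median-of-3 then [1,2,3,2,1]/9, recomputed by hand
        desp = s.copy()
        for i in range(1, 51):
            desp[i] = np.median(s[i - 1:i + 2])
        w = np.array([1, 2, 3, 2, 1], float)
        i = 25
        expected = np.dot(w, desp[i - 2:i + 3]) / w.sum()
        assert out.values[i, 0, 0] == pytest.approx(expected, abs=1e-12)

    def test_fully_masked_pixel_stays_masked(self):
        v = np.random.default_rng(1).normal(size=(52, 2, 1)) * 0.1
        mask = np.ones_like(v, bool)
        mask[:, 1, 0] = False
        cube = make_cube(v, tag="NDVI", mask=mask)
        out = vh.smooth_series(cube)
        assert not out.mask[:, 1, 0].any()
        assert out.mask[:, 0, 0].all()

    def test_even_or_tiny_window_rejected(self):
        cube = _series_cube(np.zeros(52))
        for w in (1, 4):
            with pytest.raises(ValueError):
                vh.smooth_series(cube, window_weeks=w)


class TestClimatology:
    def test_per_week_extrema_across_years(self):
        v = np.zeros((3 * 52, 1, 1))
        v[4], v[4 + 52], v[4 + 104] = 0.1, 0.3, 0.2  # week 5 of each year
        ext = vh.climatology_extrema(make_cube(v, tag="SMN"))
        assert ext.vmax[4, 0, 0] == pytest.approx(0.3)
        assert ext.vmin[4, 0, 0] == pytest.approx(0.1)

    def test_constant_field_flagged_degenerate(self):
        ext = vh.climatology_extrema(
            make_cube(np.full((156, 1, 1), 0.2), tag="SMN"))
        assert ext.degenerate.all()

    def test_seasonal_only_run_gives_flat_envelope(self):
        cfg = vh.SyntheticConfig(n_years=4, n_lat=2, n_lon=2,
                                 noise_sd_ndvi=0.0, noise_sd_bt=0.0)
        ndvi, _, _ = vh.generate_fields(cfg)
        # raw cube: every year is identical, so the envelope is flat
        ext = vh.climatology_extrema(ndvi)
        np.testing.assert_allclose(ext.vmax, ext.vmin, atol=1e-12)
        # after smoothing only the record edges (truncated kernel in the
        # first/last year) can open the envelope
        ext_sm = vh.climatology_extrema(vh.smooth_series(ndvi))
        np.testing.assert_allclose(ext_sm.vmax[2:50], ext_sm.vmin[2:50],
                                   atol=1e-12)

    def test_global_envelope_option(self):
        cfg = vh.SyntheticConfig(n_years=4, n_lat=2, n_lon=2, rng_seed=3)
        ndvi, _, _ = vh.generate_fields(cfg)
        smn = vh.smooth_series(ndvi)
        ext = vh.climatology_extrema(smn, per_week=False)
        v = smn.masked_values()
        np.testing.assert_allclose(ext.vmax[0], np.nanmax(v, axis=0))
        assert np.allclose(ext.vmax[0], ext.vmax[30])

    def test_too_few_years_rejected(self):
        with pytest.raises(ValueError):
            vh.climatology_extrema(
                make_cube(np.random.rand(104, 1, 1), tag="SMN"))


class TestIndexFormulas:
    @pytest.fixture()
    def simple(self):
        # week-1 values across 3 years: 0.1, 0.3, 0.2
        v = np.full((156, 1, 1), np.nan)
        year, week = vh.weekly_axis(2000, 3)
        vals = np.zeros(156)
        vals[week == 1] = [0.1, 0.3, 0.2]
        vals[week != 1] = np.linspace(0, 1, (week != 1).sum())
        cube = vh.WeeklyCube(vals[:, None, None], year, week, tag="SMN")
        return cube, vh.climatology_extrema(cube)

    def test_vci_endpoints_and_midpoint(self, simple):
        cube, ext = simple
        vci = vh.compute_vci(cube, ext)
        w1 = cube.week == 1
        np.testing.assert_allclose(vci.values[w1, 0, 0], [0.0, 100.0, 50.0])

    def test_tci_reversed_orientation(self, simple):
        cube, ext = simple
        smt = cube.with_values(cube.values, tag="SMT")
        tci = vh.compute_tci(smt, ext)
        w1 = cube.week == 1
        np.testing.assert_allclose(tci.values[w1, 0, 0], [100.0, 0.0, 50.0])

    def test_degenerate_pixels_masked_not_divided(self):
        cube = make_cube(np.full((156, 1, 1), 0.2), tag="SMN")
        vci = vh.compute_vci(cube, vh.climatology_extrema(cube))
        assert not vci.mask.any()

    def test_vhi_is_weighted_mean(self, index_chain):
        vci, tci = index_chain["vci"], index_chain["tci"]
        vhi = vh.compute_vhi(vci, tci, 0.5)
        ok = vhi.mask
        np.testing.assert_allclose(
            vhi.values[ok],
            0.5 * vci.values[ok] + 0.5 * tci.values[ok], atol=1e-12)

    def test_vhi_weight_one_is_vci(self, index_chain):
        vci, tci = index_chain["vci"], index_chain["tci"]
        vhi = vh.compute_vhi(vci, tci, vh.VhiWeights(1.0))
        ok = vhi.mask
        np.testing.assert_array_equal(vhi.values[ok], vci.values[ok])

    @given(a=st.floats(0.0, 1.0), x=st.floats(0.0, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_vhi_convexity_fixed_point(self, a, x):
        v = np.full((156, 1, 1), x)
        vci = make_cube(v, tag="VCI")
        tci = make_cube(v.copy(), tag="TCI")
        vhi = vh.compute_vhi(vci, tci, a)
        np.testing.assert_allclose(vhi.values, x, atol=1e-9)

    def test_misaligned_cubes_rejected(self, index_chain):
        vci = index_chain["vci"]
        short = make_cube(np.zeros((52, 1, 1)), tag="TCI")
        with pytest.raises(ValueError):
            vh.compute_vhi(vci, short)

    def test_mask_union_propagates(self):
        v = np.random.default_rng(2).uniform(0, 100, (52, 2, 2))
        m1 = np.ones_like(v, bool)
        m2 = np.ones_like(v, bool)
        m1[3, 0, 0] = False
        m2[5, 1, 1] = False
        vhi = vh.compute_vhi(make_cube(v, tag="VCI", mask=m1),
                             make_cube(v.copy(), tag="TCI", mask=m2))
        assert not vhi.mask[3, 0, 0] and not vhi.mask[5, 1, 1]


class TestIndexInvariants:
    def test_normalization_range(self, index_chain):
        for key in ("vci", "tci", "vhi"):
            cube = index_chain[key]
            vals = cube.values[cube.mask]
            assert vals.min() >= 0.0 and vals.max() <= 100.0

    def test_self_consistency_each_pixel_week_spans_0_and_100(self,
                                                              index_chain):
        vci = index_chain["vci"]
        v = vci.masked_values()
        for w in (10, 30):
            block = v[vci.week == w]  # (n_years, ny, nx)
            ok = np.isfinite(block).all(axis=0)
            assert np.allclose(np.nanmin(block, axis=0)[ok], 0.0, atol=1e-9)
            assert np.allclose(np.nanmax(block, axis=0)[ok], 100.0, atol=1e-9)

    def test_monotone_orientation(self, index_chain):
        smn, ext = index_chain["smn"], index_chain["ext_n"]
        bumped = smn.with_values(smn.values + 0.001)
        v0 = vh.compute_vci(smn, ext)
        v1 = vh.compute_vci(bumped, ext)
        both = v0.mask & v1.mask
        assert (v1.values[both] >= v0.values[both] - 1e-9).all()
        smt, ext_t = index_chain["smt"], index_chain["ext_t"]
        hot = smt.with_values(smt.values + 0.5)
        t0 = vh.compute_tci(smt, ext_t)
        t1 = vh.compute_tci(hot, ext_t)
        both = t0.mask & t1.mask
        assert (t1.values[both] <= t0.values[both] + 1e-9).all()
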