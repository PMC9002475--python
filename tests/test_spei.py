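import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import fisk, norm

import vegattrib as va
from vegattrib.spei import (
    FitError,
    LogLogisticParams,
    ScaleError,
    accumulate,
    extraterrestrial_radiation,
    fit_loglogistic,
    hargreaves_pet,
    loglogistic_cdf,
    normal_quantile_rational,
    spei_grid,
    spei_series,
    spei_transform,
)


class TestAccumulate:
    def test_window_sums(self):
        out = accumulate(np.array([1.0, 2, 3, 4]), 3)
        assert np.isnan(out[:2]).all()
        assert out[2] == 6 and out[3] == 9

    def test_scale_one_is_identity(self):
        d = np.arange(5, dtype=float)
        assert accumulate(d, 1).tolist() == d.tolist()

    def test_constant_series(self):
        out = accumulate(np.full(24, 2.0), 12)
        assert np.all(out[11:] == 24.0)

    def test_scale_longer_than_series(self):
        with pytest.raises(ScaleError):
            accumulate(np.ones(5), 6)


class TestLogLogisticFit:
    def test_recovers_known_distribution(self):
        # oracle: sample from scipy's log-logistic (fisk) and refit
        x = fisk.rvs(3.0, loc=-10.0, scale=50.0, size=5000,
                     random_state=np.random.default_rng(2))
        p = fit_loglogistic(x)
        assert not p.reflected
        assert p.shape == pytest.approx(3.0, rel=0.05)
        assert p.scale == pytest.approx(50.0, rel=0.05)
        assert p.origin == pytest.approx(-10.0, rel=0.05)

    def test_affine_shift_moves_origin_only(self):
        x = fisk.rvs(4.0, loc=0.0, scale=30.0, size=2000,
                     random_state=np.random.default_rng(5))
        p0 = fit_loglogistic(x)
        p1 = fit_loglogistic(x + 17.5)
        assert p1.origin - p0.origin == pytest.approx(17.5, abs=1e-8)
        assert p1.shape == pytest.approx(p0.shape, rel=1e-10)
        assert p1.scale == pytest.approx(p0.scale, rel=1e-10)

    def test_constant_sample_raises(self):
        with pytest.raises(FitError, match="constant"):
            fit_loglogistic(np.full(20, 7.0))

    def test_too_few_samples_raises(self):
        with pytest.raises(FitError, match="finite samples"):
            fit_loglogistic(np.arange(5, dtype=float))

    def test_left_skewed_sample_uses_mirror_fit(self, rng):
        x = -fisk.rvs(3.0, loc=0.0, scale=50.0, size=500, random_state=rng)
        p = fit_loglogistic(x)
        assert p.reflected
        z = spei_transform(np.sort(x), p)
        assert np.all(np.diff(z) >= 0)  # still monotone increasing

    def test_cdf_matches_numerically_integrated_density(self):
        # independent oracle: integrate scipy's density
        p = LogLogisticParams(3.0, 50.0, -10.0)
        xs = np.linspace(-5.0, 400.0, 9)
        mine = loglogistic_cdf(xs, p)
        ref = [quad(lambda u: fisk.pdf(u, 3.0, loc=-10.0, scale=50.0), -10.0, x)[0]
               for x in xs]
        assert np.abs(mine - np.array(ref)).max() < 1e-6


class TestTransform:
    @pytest.fixture()
    def params(self):
        return LogLogisticParams(3.0, 50.0, -10.0)

    def test_median_maps_to_zero(self, params):
        median = fisk.median(3.0, loc=-10.0, scale=50.0)
        assert abs(spei_transform(np.array([median]), params)[0]) < 0.02

    def test_strictly_increasing(self, params):
        # strict within the clamp bounds, non-decreasing everywhere
        xs = fisk.ppf(np.linspace(0.002, 0.998, 200), 3.0, loc=-10.0, scale=50.0)
        z = spei_transform(xs, params)
        assert np.all(np.diff(z) > 0)
        wide = np.linspace(-20.0, 2000.0, 300)
        assert np.all(np.diff(spei_transform(wide, params)) >= 0)

    def test_below_origin_maps_to_extreme_dry(self, params):
        z = spei_transform(np.array([-50.0]), params)
        assert z[0] == pytest.approx(-va.spei.SPEI_CLAMP)

    def test_rational_and_exact_quantiles_agree(self, params):
        xs = np.linspace(-9.0, 500.0, 500)
        za = spei_transform(xs, params, method="rational")
        zb = spei_transform(xs, params, method="exact")
        assert np.abs(za - zb).max() < 3e-3

    def test_rational_quantile_accuracy(self):
        ps = np.linspace(1e-5, 1 - 1e-5, 20001)
        err = np.abs(normal_quantile_rational(ps) - norm.ppf(ps))
        assert err.max() < 1e-3

    @pytest.mark.parametrize("value, drought", [(-1.2, True), (-1.0, False), (-0.9, False), (0.4, False)])
    def test_drought_threshold(self, value, drought):
        assert bool(va.is_drought(value)) is drought


class TestSpeiSeries:
    def test_location_invariance(self, rng):
        d = rng.normal(0.0, 30.0, size=29 * 12)
        s0 = spei_series(d)[12]
        s1 = spei_series(d + 250.0)[12]
        assert np.nanmax(np.abs(s0 - s1)) < 1e-6

    def test_first_k_minus_one_undefined(self, rng):
        d = rng.normal(0.0, 30.0, size=29 * 12)
        out = spei_series(d, scales=(6,))[6]
        assert np.isnan(out[:5]).all()
        assert np.isfinite(out[5:]).all()


class TestSpeiGrid:
    def test_standardization_contract(self, small_scene):
        grids = spei_grid(small_scene.pre, small_scene.pet, scales=(1, 12))
        for k, g in grids.items():
            for m in range(12):
                sample = g.data[:, m].reshape(g.n_years, -1)
                mean = np.nanmean(sample, axis=0)
                sd = np.nanstd(sample, axis=0)
                ok = np.isfinite(mean)
                assert np.abs(mean[ok]).max() < 0.05
                assert sd[ok].min() > 0.9 and sd[ok].max() < 1.1

    def test_all_missing_pixel_propagates(self):
        cfg = va.SyntheticConfig(n_rows=4, n_cols=4, seed=14)
        tem, pre, pet = va.generate_climate(cfg)
        pre.data[:, :, 0, 0] = np.nan
        out = spei_grid(pre, pet, scales=(3,))[3]
        assert np.isnan(out.data[:, :, 0, 0]).all()
        assert np.isfinite(out.data[:, 3:, 1, 1]).any()

    def test_shape_mismatch_raises(self, small_scene):
        other = va.MonthlyGrid(np.zeros((29, 12, 3, 3)))
        with pytest.raises(Exception):
            spei_grid(small_scene.pre, other)

    def test_drying_trend_gives_negative_spei12_slopes(self):
        cfg = va.trended_climate_config(n_rows=8, n_cols=8, seed=4)
        _, pre, pet = va.generate_climate(cfg)
        s12 = spei_grid(pre, pet, scales=(12,))[12]
        from vegattrib.trends import trend_grid
        tg = trend_grid(s12.annual_mean())
        assert np.mean(tg.slope < 0) > 0.95


class TestHargreaves:
    def test_formula_value(self):
        # PET/day = 0.0023 * Ra * (T+17.8) * sqrt(range); direct evaluation
        pet = hargreaves_pet(20.0, 15.0, 25.0, latitude=0.0, month=3)
        ra = extraterrestrial_radiation(0.0, 3)
        assert pet == pytest.approx(0.0023 * ra * 37.8 * np.sqrt(10) * 31, rel=1e-12)

    def test_zero_at_minus_17_8(self):
        assert hargreaves_pet(-17.8, -20.0, -15.0, 45.0, 6) == 0.0

    def test_negative_clamped(self):
        assert hargreaves_pet(-30.0, -35.0, -25.0, 45.0, 1) == 0.0

    def test_tmax_below_tmin_raises(self):
        with pytest.raises(ValueError):
            hargreaves_pet(10.0, 12.0, 8.0, 45.0, 5)

    def test_equinox_radiation_peaks_near_equator(self):
        lats = np.linspace(-60, 60, 241)
        ra = extraterrestrial_radiation(lats, 3)
        peak = lats[np.argmax(ra)]
        assert abs(peak) < 10
        assert extraterrestrial_radiation(0.0, 3) > 0.97 * ra.max()
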