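import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vegattrib as va
from vegattrib.restrend import (
    CollinearityError,
    Scenario,
    attribute,
    attribution_grid,
    fit_climate_model,
    residual_trends,
)


def _series(slope, n=29, rng=None, sd=0.0):
    t = np.arange(n, dtype=float)
    x = slope * t
    if sd:
        x = x + rng.normal(0, sd, n)
    return x


class TestClimateModelFit:
    def test_noiseless_exact_recovery(self, rng):
        n = 29
        pre = rng.normal(80, 10, n)
        pet = rng.normal(60, 5, n)
        y = 0.3 + 0.001 * pre - 0.0005 * pet
        fit = fit_climate_model(y, pre, pet)
        assert fit.a == pytest.approx(0.001, abs=1e-9)
        assert fit.b == pytest.approx(-0.0005, abs=1e-9)
        assert np.abs(fit.ndvi_res).max() < 1e-12

    def test_decomposition_identity_exact(self, small_scene):
        sc = small_scene
        fit = fit_climate_model(sc.ndvi.growing_season_mean(),
                                sc.pre.growing_season_mean(),
                                sc.pet.growing_season_mean())
        resid = fit.ndvi_obs - (fit.ndvi_pre + fit.ndvi_res)
        assert np.nanmax(np.abs(resid)) < 1e-12

    def test_collinear_predictors_raise(self, rng):
        pre = rng.normal(size=29)
        y = rng.normal(size=29)
        with pytest.raises(CollinearityError):
            fit_climate_model(y, pre, 2.0 * pre + 1.0)

    def test_unbiased_over_seeds(self):
        # Monte-Carlo: mean recovered coefficient within 3 SE of truth
        a_true, b_true = 0.004, -0.0015
        est = []
        for seed in range(120):
            rng = np.random.default_rng(seed)
            pre = rng.normal(100, 9, 29)
            pet = rng.normal(80, 5, 29)
            y = 0.1 + a_true * pre + b_true * pet + rng.normal(0, 0.02, 29)
            est.append(fit_climate_model(y, pre, pet).a)
        est = np.asarray(est, dtype=float)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - a_true) < 3 * se


def _orthogonal_to_trend(x, n):
    """Remove the in-sample (1, t) component so the regressor carries no
    trend; the residual-trend decomposition is then exact."""
    t = np.arange(n, dtype=float)
    design = np.stack([np.ones(n), t], axis=1)
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta


class TestResidualTrends:
    def test_human_trend_lands_in_residual(self, rng):
        n = 29
        pre = 80 + _orthogonal_to_trend(rng.normal(0, 10, n), n)
        pet = 60 + _orthogonal_to_trend(rng.normal(0, 5, n), n)
        y = 0.3 + 0.001 * pre - 0.0005 * pet + 0.002 * np.arange(n)
        rt = residual_trends(fit_climate_model(y, pre, pet))
        assert rt.slope_res == pytest.approx(0.002, abs=1e-9)

    def test_pure_climate_gives_zero_residual_slope(self, rng):
        n = 29
        pre = rng.normal(80, 10, n) - 1.0 * np.arange(n)
        pet = rng.normal(60, 5, n)
        y = 0.3 + 0.001 * pre - 0.0005 * pet
        rt = residual_trends(fit_climate_model(y, pre, pet))
        assert rt.slope_res == pytest.approx(0.0, abs=1e-9)

    def test_ols_slope_additivity(self, small_scene):
        sc = small_scene
        fit = fit_climate_model(sc.ndvi.growing_season_mean(),
                                sc.pre.growing_season_mean(),
                                sc.pet.growing_season_mean())
        rt = residual_trends(fit)
        from vegattrib.trends import trend_grid
        slope_obs = trend_grid(fit.ndvi_obs).ols_slope
        assert np.nanmax(np.abs(rt.slope_pre + rt.slope_res - slope_obs)) < 1e-12


class TestAttributionRules:
    @pytest.mark.parametrize("obs, pre, res, climate, human, scenario", [
        (0.002, 0.0005, 0.0015, 25.0, 75.0, Scenario.BOTH_IMPROVED),
        (0.001, 0.0015, -0.0005, 100.0, 0.0, Scenario.CLIMATE_IMPROVED),
        (0.001, -0.0004, 0.0014, 0.0, 100.0, Scenario.HUMAN_IMPROVED),
        (-0.002, -0.0005, -0.0015, 25.0, 75.0, Scenario.BOTH_DEGRADED),
        (-0.001, -0.0012, 0.0002, 100.0, 0.0, Scenario.CLIMATE_DEGRADED),
        (-0.001, 0.0004, -0.0014, 0.0, 100.0, Scenario.HUMAN_DEGRADED),
    ])
    def test_six_scenarios(self, obs, pre, res, climate, human, scenario):
        s, c, h = attribute(obs, pre, res)
        assert s == scenario
        assert c == pytest.approx(climate)
        assert h == pytest.approx(human)

    def test_no_change_sentinel(self):
        s, c, h = attribute(0.0, 0.001, -0.001)
        assert s == Scenario.NO_CHANGE
        assert np.isnan(c) and np.isnan(h)

    @given(st.floats(1e-5, 1e-2), st.floats(0.0, 1.0))
    @settings(deadline=None, max_examples=60)
    def test_contributions_sum_to_100_and_bounded(self, obs, frac):
        # additive decomposition with both components sharing the sign
        pre = frac * obs
        res = obs - pre
        for sign in (1.0, -1.0):
            _, c, h = attribute(sign * obs, sign * pre, sign * res)
            assert c + h == pytest.approx(100.0)
            assert -1e-9 <= c <= 100 + 1e-9 and -1e-9 <= h <= 100 + 1e-9

    def test_strict_mode_gates_insignificant_components(self):
        s, c, h = attribute(0.002, 0.0005, 0.0015,
                            z_pre=1.0, z_res=4.0, strict=True)
        assert s == Scenario.HUMAN_IMPROVED and h == 100.0
        s2, _, _ = attribute(0.002, 0.0005, 0.0015,
                             z_pre=2.5, z_res=4.0, strict=True)
        assert s2 == Scenario.BOTH_IMPROVED


class TestAttributionGrid:
    def test_truth_scenarios_differ_between_regions(self, small_scene):
        t = small_scene.truth
        improved = t.loc[t.h > 0, "scenario"].unique()
        degraded = t.loc[t.h < 0, "scenario"].unique()
        assert set(improved) & {Scenario.BOTH_IMPROVED, Scenario.HUMAN_IMPROVED}
        assert set(degraded) & {Scenario.BOTH_DEGRADED, Scenario.HUMAN_DEGRADED}
        assert not set(improved) & set(degraded)

    def test_scenario_recovery_on_scene(self, small_scene):
        sc = small_scene
        att = attribution_grid(sc.ndvi, sc.pre, sc.pet, strict=True)
        ok = (~sc.truth.truncated_gs & ~sc.truth.clipped).values
        acc = np.mean(att.scenario.reshape(-1)[ok]
                      == sc.truth.scenario_strict.values[ok])
        assert acc >= 0.9

    def test_no_human_trend_attributes_to_climate(self):
        # noise-free NDVI with h = 0: the residual is identically zero, so
        # every attributed pixel lands in a climate-only row
        cfg = va.SyntheticConfig(n_rows=10, n_cols=10, seed=6,
                                 human_trend_map={}, noise_sd=0.0)
        sc = va.generate_scene(cfg)
        att = attribution_grid(sc.ndvi, sc.pre, sc.pet)
        attributed = att.scenario != Scenario.NO_CHANGE
        assert attributed.any()
        assert np.isin(att.scenario[attributed],
                       [Scenario.CLIMATE_IMPROVED, Scenario.CLIMATE_DEGRADED]).all()
        assert np.nanmax(att.contrib_human[attributed]) == 0.0

    def test_region_permutation_permutes_summaries(self, small_scene):
        sc = small_scene
        att1 = attribution_grid(sc.ndvi, sc.pre, sc.pet, landcover=sc.landcover)
        perm = {1: 4, 2: 3, 3: 1, 4: 2}
        relabeled = np.vectorize(perm.get)(sc.landcover)
        att2 = attribution_grid(sc.ndvi, sc.pre, sc.pet, landcover=relabeled)
        s1 = att1.summaries.set_index(["class", "direction"])
        s2 = att2.summaries.set_index(["class", "direction"])
        for (cls, direc), row in s1.iterrows():
            other = s2.loc[(perm[cls], direc)]
            assert row["n_pixels"] == other["n_pixels"]
            assert row["mean_contrib_climate"] == pytest.approx(
                other["mean_contrib_climate"])
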