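"""Residual-trend (RESTREND) separation of climate and human NDVI drivers.

Growing-season NDVI is regressed on growing-season precipitation and
potential evapotranspiration (ordinary least squares with intercept); the
fitted values are the climate-predicted component NDVI_pre and the
residuals NDVI_res = NDVI_obs - NDVI_pre carry the non-climatic (human)
signal.  The OLS trend slopes of the three series -- which add exactly,
slope_pre + slope_res = slope_obs -- feed a six-scenario rule table that
assigns each pixel a climate and a human contribution percentage summing
to 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grids import GROWING_SEASON, MonthlyGrid
from . import trends as _trends

#: |slope_obs| below this (NDVI/year) is treated as no change, avoiding
#: contribution ratios blowing up on a near-zero denominator.
NO_CHANGE_EPS: float = 1e-6


class Scenario(IntEnum):
    """Attribution scenarios: sign pattern of (obs, pre, res) slopes."""

    NO_CHANGE = 0
    BOTH_IMPROVED = 1        # obs>0, pre>0, res>0: shared improvement
    CLIMATE_IMPROVED = 2     # obs>0, pre>0, res<=0: climate alone improved
    HUMAN_IMPROVED = 3       # obs>0, pre<=0, res>0: human activity alone improved
    BOTH_DEGRADED = 4        # obs<0, pre<0, res<0: shared degradation
    CLIMATE_DEGRADED = 5     # obs<0, pre<0, res>=0: climate alone degraded
    HUMAN_DEGRADED = 6       # obs<0, pre>=0, res<0: human activity alone degraded


class CollinearityError(ValueError):
    """Climate predictors are collinear; the regression is undefined."""


# --------------------------------------------------------------------------
# climate model fit
# --------------------------------------------------------------------------

@dataclass
class ClimateModelFit:
    """OLS fit of NDVI on PRE and PET (with intercept), per pixel.

    ``ndvi_obs = ndvi_pre + ndvi_res`` holds exactly, year by year.
    Arrays are (n_years, ...) for the series and (...) for coefficients;
    NaN marks pixels flagged collinear or unfittable.
    """

    a: np.ndarray           # NDVI per mm of PRE
    b: np.ndarray           # NDVI per mm of PET
    intercept: np.ndarray
    ndvi_pre: np.ndarray
    ndvi_res: np.ndarray
    ndvi_obs: np.ndarray


def fit_climate_model(
    ndvi_gs: np.ndarray, pre_gs: np.ndarray, pet_gs: np.ndarray
) -> ClimateModelFit:
    """Least-squares NDVI ~ a*PRE + b*PET + intercept, vectorized per pixel.

    Inputs share shape (n_years,) or (n_years, n_rows, n_cols).  Pixels
    whose predictor cross-product matrix is numerically singular are
    flagged NaN; a scalar (1-D) call raises :class:`CollinearityError`
    instead.
    """
    y = np.asarray(ndvi_gs, dtype=float)
    p = np.asarray(pre_gs, dtype=float)
    e = np.asarray(pet_gs, dtype=float)
    if not (y.shape == p.shape == e.shape):
        raise ValueError("ndvi, pre, pet must share shape")
    one_d = y.ndim == 1
    n = y.shape[0]
    if n < 5:
        raise ValueError("need >= 5 years to fit the climate model")
    yf = y.reshape(n, -1)
    x = np.stack([np.ones_like(yf), p.reshape(n, -1), e.reshape(n, -1)], axis=-1)  # (n, m, 3)

    xtx = np.einsum("nmi,nmj->mij", x, x)
    xty = np.einsum("nmi,nm->mi", x, yf)
    # guard singular systems pixel-wise
    det = np.linalg.det(xtx)
    scale = np.abs(xtx).max(axis=(1, 2)) ** 3 + 1e-300
    ok = np.isfinite(det) & (np.abs(det) > 1e-12 * scale) & np.isfinite(yf).all(axis=0) \
        & np.isfinite(x).all(axis=(0, 2))
    beta = np.full((yf.shape[1], 3), np.nan)
    if ok.any():
        beta[ok] = np.linalg.solve(xtx[ok], xty[ok][..., None])[..., 0]
    if one_d and not ok[0]:
        raise CollinearityError("predictors are collinear; climate model undefined")

    pred = np.einsum("nmi,mi->nm", x, beta)
    res = yf - pred
    shape = y.shape[1:]
    return ClimateModelFit(
        a=beta[:, 1].reshape(shape),
        b=beta[:, 2].reshape(shape),
        intercept=beta[:, 0].reshape(shape),
        ndvi_pre=pred.reshape(y.shape),
        ndvi_res=res.reshape(y.shape),
        ndvi_obs=y,
    )


@dataclass
class ResidualTrends:
    slope_pre: np.ndarray
    slope_res: np.ndarray
    z_pre: np.ndarray
    z_res: np.ndarray


def residual_trends(fit: ClimateModelFit) -> ResidualTrends:
    """OLS slopes (used for attribution) and Mann-Kendall Z of the
    climate-predicted and residual series."""
    one_d = fit.ndvi_pre.ndim == 1

    def _as_grid(x: np.ndarray) -> np.ndarray:
        return x.reshape(x.shape[0], 1, 1) if one_d else x

    tg_pre = _trends.trend_grid(_as_grid(fit.ndvi_pre))
    tg_res = _trends.trend_grid(_as_grid(fit.ndvi_res))
    if one_d:
        return ResidualTrends(
            slope_pre=float(tg_pre.ols_slope[0, 0]),
            slope_res=float(tg_res.ols_slope[0, 0]),
            z_pre=float(tg_pre.z[0, 0]),
            z_res=float(tg_res.z[0, 0]),
        )
    return ResidualTrends(tg_pre.ols_slope, tg_res.ols_slope, tg_pre.z, tg_res.z)


# --------------------------------------------------------------------------
# scenario rules
# --------------------------------------------------------------------------

def attribute(
    slope_obs: np.ndarray | float,
    slope_pre: np.ndarray | float,
    slope_res: np.ndarray | float,
    z_pre: np.ndarray | None = None,
    z_res: np.ndarray | None = None,
    strict: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign each pixel a scenario and climate/human contribution percentages.

    When observed NDVI changed (|slope_obs| above the no-change epsilon)
    and both components share its sign, contributions are the slope ratios
    100*slope_pre/slope_obs and 100*slope_res/slope_obs; when only one
    component shares the sign, that driver takes 100%.  Contributions sum
    to 100 for every attributed pixel.  ``strict`` zeroes a component's
    sign when its Mann-Kendall score is insignificant (|Z| <= 1.96), so
    only significant component trends count as "a trend exists".
    """
    obs = np.asarray(slope_obs, dtype=float)
    pre = np.asarray(slope_pre, dtype=float)
    res = np.asarray(slope_res, dtype=float)
    obs, pre, res = np.broadcast_arrays(obs, pre, res)

    # component slopes inside the no-change band carry no usable sign
    sign_pre = np.where(np.abs(pre) > NO_CHANGE_EPS, np.sign(pre), 0.0)
    sign_res = np.where(np.abs(res) > NO_CHANGE_EPS, np.sign(res), 0.0)
    if strict:
        if z_pre is None or z_res is None:
            raise ValueError("strict mode needs z_pre and z_res")
        sign_pre = np.where(np.abs(z_pre) > _trends.SIGNIFICANCE_Z, sign_pre, 0.0)
        sign_res = np.where(np.abs(z_res) > _trends.SIGNIFICANCE_Z, sign_res, 0.0)

    scenario = np.zeros(obs.shape, dtype=np.int8)
    climate = np.full(obs.shape, np.nan)
    human = np.full(obs.shape, np.nan)

    inc = obs > NO_CHANGE_EPS
    dec = obs < -NO_CHANGE_EPS

    both_i = inc & (sign_pre > 0) & (sign_res > 0)
    clim_i = inc & (sign_pre > 0) & (sign_res <= 0)
    hum_i = inc & (sign_pre <= 0)
    both_d = dec & (sign_pre < 0) & (sign_res < 0)
    clim_d = dec & (sign_pre < 0) & (sign_res >= 0)
    hum_d = dec & (sign_pre >= 0)

    scenario[both_i] = Scenario.BOTH_IMPROVED
    scenario[clim_i] = Scenario.CLIMATE_IMPROVED
    scenario[hum_i] = Scenario.HUMAN_IMPROVED
    scenario[both_d] = Scenario.BOTH_DEGRADED
    scenario[clim_d] = Scenario.CLIMATE_DEGRADED
    scenario[hum_d] = Scenario.HUMAN_DEGRADED

    ratio = np.zeros_like(obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        np.divide(pre, obs, out=ratio, where=inc | dec)
    shared = both_i | both_d
    climate[shared] = 100.0 * ratio[shared]
    human[shared] = 100.0 - climate[shared]
    climate[clim_i | clim_d] = 100.0
    human[clim_i | clim_d] = 0.0
    climate[hum_i | hum_d] = 0.0
    human[hum_i | hum_d] = 100.0

    invalid = ~(np.isfinite(obs) & np.isfinite(pre) & np.isfinite(res))
    scenario[invalid] = Scenario.NO_CHANGE
    climate[invalid] = np.nan
    human[invalid] = np.nan
    return scenario, climate, human


# --------------------------------------------------------------------------
# grid-level attribution
# --------------------------------------------------------------------------

@dataclass
class AttributionResult:
    """Per-pixel attribution of observed NDVI change."""

    slope_obs: np.ndarray
    slope_pre: np.ndarray
    slope_res: np.ndarray
    scenario: np.ndarray
    contrib_climate: np.ndarray
    contrib_human: np.ndarray
    fit: ClimateModelFit
    summaries: pd.DataFrame | None = None


def _role_summary(att: "AttributionResult", classes: np.ndarray,
                  label: str) -> pd.DataFrame:
    """Mean relative role of each driver per class and change direction."""
    rows = []
    attributed = att.scenario != Scenario.NO_CHANGE
    direction = np.where(att.slope_obs > 0, "increase", "decrease")
    for cls in np.unique(classes[np.isfinite(np.asarray(classes, dtype=float))]):
        for direc in ("increase", "decrease"):
            sel = attributed & (classes == cls) & (direction == direc)
            if not sel.any():
                continue
            rows.append({
                "grouping": label,
                "class": cls,
                "direction": direc,
                "n_pixels": int(sel.sum()),
                "mean_contrib_climate": float(np.nanmean(att.contrib_climate[sel])),
                "mean_contrib_human": float(np.nanmean(att.contrib_human[sel])),
            })
    return pd.DataFrame(rows)


def attribution_grid(
    ndvi: MonthlyGrid,
    pre: MonthlyGrid,
    pet: MonthlyGrid,
    months: Sequence[int] = GROWING_SEASON,
    landcover: np.ndarray | None = None,
    climregion: np.ndarray | None = None,
    rmax_scale: np.ndarray | None = None,
    strict: bool = False,
) -> AttributionResult:
    """Full RESTREND attribution of a scene, with zonal role summaries.

    Pools are pixel means (unweighted) per class and per change direction;
    grouping masks are optional.
    """
    ndvi.require_same_layout(pre)
    ndvi.require_same_layout(pet)
    y = ndvi.annual_mean(months)
    p = pre.annual_mean(months)
    e = pet.annual_mean(months)
    fit = fit_climate_model(y, p, e)
    rt = residual_trends(fit)
    tg_obs = _trends.trend_grid(y)
    slope_obs = tg_obs.ols_slope
    scenario, climate, human = attribute(
        slope_obs, rt.slope_pre, rt.slope_res,
        z_pre=rt.z_pre, z_res=rt.z_res, strict=strict,
    )
    att = AttributionResult(slope_obs, rt.slope_pre, rt.slope_res,
                            scenario, climate, human, fit)
    frames = []
    for classes, label in ((landcover, "landcover"), (climregion, "climregion"),
                           (rmax_scale, "rmax_scale")):
        if classes is not None:
            frames.append(_role_summary(att, np.asarray(classes), label))
    if frames:
        att.summaries = pd.concat(frames, ignore_index=True)
    return att
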