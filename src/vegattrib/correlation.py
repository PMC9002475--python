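"""NDVI-water-availability correlation structure across timescales.

For each growing-season month i and SPEI timescale j, the Pearson
correlation across years between monthly NDVI and SPEI-j (accumulation
window ending in month i) is computed per pixel.  From the month x scale
field the coefficient of maximal absolute value is extracted per scale and
overall -- selection is by |r| but the SIGN IS RETAINED -- along with the
timescale at which it is attained and the maximum water surplus period
(largest scale still negatively correlated).  First-order partial
correlations of growing-season NDVI with PRE (controlling PET) and PET
(controlling PRE) quantify each climate driver's separate association.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np
from scipy.stats import t as _t_dist

from .grids import GROWING_SEASON, MonthlyGrid

#: Minimum year pairs for a defined Pearson coefficient.
MIN_YEARS: int = 10


# --------------------------------------------------------------------------
# Pearson correlation across years, vectorized with pairwise NaN handling
# --------------------------------------------------------------------------

def _pearson_over_years(a: np.ndarray, b: np.ndarray, min_n: int = MIN_YEARS) -> np.ndarray:
    """Pearson r along axis 0; NaNs removed pairwise; undefined -> NaN."""
    ok = np.isfinite(a) & np.isfinite(b)
    n = ok.sum(axis=0)
    aa = np.where(ok, a, 0.0)
    bb = np.where(ok, b, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = aa.sum(axis=0) / n
        mb = bb.sum(axis=0) / n
        da = np.where(ok, a - ma, 0.0)
        db = np.where(ok, b - mb, 0.0)
        cov = (da * db).sum(axis=0)
        va = (da * da).sum(axis=0)
        vb = (db * db).sum(axis=0)
        r = cov / np.sqrt(va * vb)
    r = np.where((n >= min_n) & (va > 0) & (vb > 0), r, np.nan)
    return np.clip(r, -1.0, 1.0)


def pearson_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of a Pearson coefficient with n-2 df."""
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    return 2.0 * _t_dist.sf(np.abs(t), df)


# --------------------------------------------------------------------------
# month x scale correlation field
# --------------------------------------------------------------------------

@dataclass
class CorrelationField:
    """Per-pixel correlation structure of NDVI with multi-scale SPEI.

    ``r`` has shape (n_months, n_scales, n_rows, n_cols); NaN marks
    undefined coefficients (short records or zero variance).
    """

    r: np.ndarray
    months: tuple[int, ...]
    scales: tuple[int, ...]
    n_years: int


def monthly_correlations(
    ndvi: MonthlyGrid,
    spei: Mapping[int, MonthlyGrid],
    months: Sequence[int] = GROWING_SEASON,
) -> CorrelationField:
    """Pearson r of NDVI(year, i) with SPEI_j(year, i) across years.

    Each (month, scale) coefficient correlates same-calendar-month pairs
    across years, so it measures the interannual response of that month's
    greenness to the water balance accumulated over the preceding j months.
    """
    scales = tuple(sorted(spei))
    for g in spei.values():
        ndvi.require_same_layout(g)
    nr, nc = ndvi.grid_shape
    out = np.full((len(months), len(scales), nr, nc), np.nan)
    for si, k in enumerate(scales):
        sg = spei[k]
        for mi, m in enumerate(months):
            a = ndvi.data[:, m - 1]
            b = sg.data[:, m - 1]
            out[mi, si] = _pearson_over_years(a, b)
    return CorrelationField(out, tuple(months), scales, ndvi.n_years)


def rmax_by_scale(field: CorrelationField) -> np.ndarray:
    """Per scale, the signed coefficient of maximal |r| over months.

    Ties break toward the earliest month.  Shape (n_scales, n_rows, n_cols).
    """
    absr = np.abs(field.r)
    absr_f = np.where(np.isfinite(absr), absr, -np.inf)
    idx = np.argmax(absr_f, axis=0)  # first occurrence wins ties
    signed = np.take_along_axis(field.r, idx[None], axis=0)[0]
    all_undef = ~np.isfinite(field.r).any(axis=0)
    return np.where(all_undef, np.nan, signed)


def rmax_overall(by_scale: np.ndarray, scales: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Signed overall maximum-|r| coefficient and its timescale.

    ``by_scale`` has shape (n_scales, ...); scales must be ascending so the
    tie rule (shortest scale) matches first-occurrence argmax.  Returns
    (rmax, rmax_scale); rmax_scale is NaN where everything is undefined.
    """
    scales = np.asarray(list(scales))
    if np.any(np.diff(scales) <= 0):
        raise ValueError("scales must be strictly ascending")
    absr = np.where(np.isfinite(by_scale), np.abs(by_scale), -np.inf)
    idx = np.argmax(absr, axis=0)
    rmax = np.take_along_axis(by_scale, idx[None], axis=0)[0]
    scale = scales[idx].astype(float)
    all_undef = ~np.isfinite(by_scale).any(axis=0)
    return np.where(all_undef, np.nan, rmax), np.where(all_undef, np.nan, scale)


def max_water_surplus_period(by_scale: np.ndarray, scales: Sequence[int]) -> np.ndarray:
    """Largest timescale whose coefficient is negative; 0 if none.

    A negative NDVI-SPEI coefficient at scale k means drying over k months
    still associates with higher NDVI (water surplus); the largest such k
    is the longest window over which drying remains beneficial.
    """
    scales = np.asarray(list(scales))
    out = np.zeros(by_scale.shape[1:], dtype=float)
    for si in range(len(scales)):  # ascending: later scales overwrite
        neg = by_scale[si] < 0
        out[neg] = scales[si]
    return out


# --------------------------------------------------------------------------
# partial correlations
# --------------------------------------------------------------------------

@dataclass
class PartialCorrelationField:
    """First-order partial correlations of NDVI with PRE and PET."""

    r_pre: np.ndarray   # NDVI-PRE controlling PET
    r_pet: np.ndarray   # NDVI-PET controlling PRE
    p_pre: np.ndarray
    p_pet: np.ndarray
    n_years: int


def _partial(rxy: np.ndarray, rxz: np.ndarray, ryz: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt((1.0 - rxz**2) * (1.0 - ryz**2))
        r = (rxy - rxz * ryz) / denom
    r = np.where(denom > 0, r, np.nan)  # |r|=1 controls -> collinear, undefined
    return np.clip(r, -1.0, 1.0)


def partial_correlation(
    ndvi_gs: np.ndarray, pre_gs: np.ndarray, pet_gs: np.ndarray
) -> PartialCorrelationField:
    """Partial r of annual growing-season NDVI with PRE and with PET.

    Arrays share shape (n_years, ...).  Uses the first-order recursion
    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2)) and a
    two-sided t-test with n-3 degrees of freedom.
    """
    ndvi_gs = np.asarray(ndvi_gs, dtype=float)
    n = ndvi_gs.shape[0]
    if n < 5:
        raise ValueError("partial correlation needs >= 5 years")
    r_np = _pearson_over_years(ndvi_gs, pre_gs, min_n=5)
    r_ne = _pearson_over_years(ndvi_gs, pet_gs, min_n=5)
    r_pe = _pearson_over_years(pre_gs, pet_gs, min_n=5)
    r_pre = _partial(r_np, r_ne, r_pe)
    r_pet = _partial(r_ne, r_np, r_pe)
    df = n - 3
    with np.errstate(invalid="ignore", divide="ignore"):
        t_pre = r_pre * np.sqrt(df / (1.0 - r_pre**2))
        t_pet = r_pet * np.sqrt(df / (1.0 - r_pet**2))
    p_pre = 2.0 * _t_dist.sf(np.abs(t_pre), df)
    p_pet = 2.0 * _t_dist.sf(np.abs(t_pet), df)
    return PartialCorrelationField(r_pre, r_pet, p_pre, p_pet, n)
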