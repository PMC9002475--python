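"""Per-pixel and per-series trend magnitude, significance and smoothing.

Trend magnitude comes from the Theil-Sen estimator (median of pairwise
slopes) and the OLS slope; significance from the Mann-Kendall rank test
with its tie-corrected variance; the 4-way category splits at the fixed
two-sided 1.96 threshold.  A 5-year centered moving average is provided
for smoothing annual series.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

#: Two-sided significance threshold on the standardized Mann-Kendall score.
SIGNIFICANCE_Z: float = 1.96


class InsufficientDataError(ValueError):
    """Too few finite values for the requested statistic."""


class TrendCategory(IntEnum):
    """Sign/significance classes of a monotonic trend."""

    SIGNIFICANT_DECREASE = -2
    DECREASE = -1
    NO_CHANGE = 0
    INCREASE = 1
    SIGNIFICANT_INCREASE = 2


# --------------------------------------------------------------------------
# scalar statistics
# --------------------------------------------------------------------------

def theil_sen(series: np.ndarray) -> float:
    """Median of all pairwise slopes (x_j - x_i)/(j - i), i < j.

    Missing values are skipped pairwise; the year index of each value is
    its position in the series.
    """
    x = np.asarray(series, dtype=float)
    t = np.arange(x.size, dtype=float)
    ok = np.isfinite(x)
    if ok.sum() < 2:
        raise InsufficientDataError("Theil-Sen needs >= 2 finite values")
    x, t = x[ok], t[ok]
    dx = x[None, :] - x[:, None]
    dt = t[None, :] - t[:, None]
    iu = np.triu_indices(x.size, k=1)
    return float(np.median(dx[iu] / dt[iu]))


@dataclass(frozen=True)
class MannKendallResult:
    s: float
    var_s: float
    z: float


def _mk_var(n: int, tie_sizes: np.ndarray) -> float:
    base = n * (n - 1) * (2 * n + 5)
    ties = np.sum(tie_sizes * (tie_sizes - 1) * (2 * tie_sizes + 5))
    return (base - ties) / 18.0


def mann_kendall(series: np.ndarray) -> MannKendallResult:
    """Mann-Kendall S, its tie-corrected variance, and the standardized Z.

    Z uses the +/-1 continuity correction; a fully tied series (variance
    zero) has Z defined as 0.
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 3:
        raise InsufficientDataError("Mann-Kendall needs >= 3 finite values")
    s = float(np.sum(np.sign(x[None, :] - x[:, None])[np.triu_indices(n, k=1)]))
    _, counts = np.unique(x, return_counts=True)
    var_s = _mk_var(n, counts[counts > 1])
    if var_s <= 0:
        return MannKendallResult(s, 0.0, 0.0)
    if s > 0:
        z = (s - 1.0) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1.0) / np.sqrt(var_s)
    else:
        z = 0.0
    return MannKendallResult(s, var_s, float(z))


def linear_trend(series: np.ndarray) -> float:
    """Ordinary least-squares slope against the year index."""
    x = np.asarray(series, dtype=float)
    t = np.arange(x.size, dtype=float)
    ok = np.isfinite(x)
    if ok.sum() < 2:
        raise InsufficientDataError("OLS slope needs >= 2 finite values")
    x, t = x[ok], t[ok]
    tc = t - t.mean()
    return float(np.sum(tc * (x - x.mean())) / np.sum(tc * tc))


def classify_trend(z: float, slope: float) -> TrendCategory:
    """4-way category at the fixed 1.96 threshold.

    Z = 0 falls back on the slope sign; a fully constant series (Z = 0 and
    slope = 0) gets the distinct NO_CHANGE sentinel, since attribution
    needs a sign and a constant series has none.
    """
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    if z > SIGNIFICANCE_Z:
        return TrendCategory.SIGNIFICANT_INCREASE
    if z < -SIGNIFICANCE_Z:
        return TrendCategory.SIGNIFICANT_DECREASE
    if z > 0:
        return TrendCategory.INCREASE
    if z < 0:
        return TrendCategory.DECREASE
    if slope > 0:
        return TrendCategory.INCREASE
    if slope < 0:
        return TrendCategory.DECREASE
    return TrendCategory.NO_CHANGE


def moving_average(series: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving mean; edges use the available shorter window."""
    x = np.asarray(series, dtype=float)
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if window > x.size:
        raise ValueError(f"window {window} exceeds series length {x.size}")
    half = (window - 1) // 2
    out = np.empty_like(x)
    for i in range(x.size):
        lo = max(0, i - half)
        hi = min(x.size, i + window - half)
        seg = x[lo:hi]
        seg = seg[np.isfinite(seg)]
        out[i] = seg.mean() if seg.size else np.nan
    return out


# --------------------------------------------------------------------------
# gridded trends
# --------------------------------------------------------------------------

@dataclass
class TrendGrid:
    """Per-pixel trend results for an annual raster stack."""

    slope: np.ndarray       # Theil-Sen, units per year
    z: np.ndarray           # Mann-Kendall standardized score
    ols_slope: np.ndarray   # least-squares slope, units per year
    category: np.ndarray    # TrendCategory values (int8); NO_CHANGE where invalid
    valid: np.ndarray       # bool, pixels meeting the minimum-years requirement


def _ts_slope_grid(x: np.ndarray) -> np.ndarray:
    """Vectorized Theil-Sen over axis 0 of (n_years, npix), complete data."""
    n = x.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    slopes = (x[ju] - x[iu]) / (ju - iu)[:, None]
    return np.median(slopes, axis=0)


def _mk_z_grid(x: np.ndarray) -> np.ndarray:
    """Vectorized Mann-Kendall Z over axis 0 of (n_years, npix)."""
    n, npix = x.shape
    s = np.zeros(npix)
    for i in range(n - 1):
        s += np.sign(x[i + 1:] - x[i]).sum(axis=0)
    base_var = _mk_var(n, np.array([], dtype=int))
    var = np.full(npix, base_var)
    # tie correction only where ties occur (rare for float data)
    xs = np.sort(x, axis=0)
    has_tie = np.any(np.diff(xs, axis=0) == 0, axis=0)
    for p in np.flatnonzero(has_tie):
        _, counts = np.unique(x[:, p], return_counts=True)
        var[p] = _mk_var(n, counts[counts > 1])
    z = np.zeros(npix)
    pos, neg = (s > 0) & (var > 0), (s < 0) & (var > 0)
    z[pos] = (s[pos] - 1.0) / np.sqrt(var[pos])
    z[neg] = (s[neg] + 1.0) / np.sqrt(var[neg])
    return z


def _ols_slope_grid(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    t = np.arange(n, dtype=float)
    tc = t - t.mean()
    return tc @ (x - x.mean(axis=0)) / np.sum(tc * tc)


def classify_trend_grid(z: np.ndarray, slope: np.ndarray) -> np.ndarray:
    """Vectorized trend classification; returns int8 TrendCategory values."""
    cat = np.zeros(z.shape, dtype=np.int8)
    cat[z > 0] = TrendCategory.INCREASE
    cat[z < 0] = TrendCategory.DECREASE
    cat[z > SIGNIFICANCE_Z] = TrendCategory.SIGNIFICANT_INCREASE
    cat[z < -SIGNIFICANCE_Z] = TrendCategory.SIGNIFICANT_DECREASE
    tie = z == 0
    cat[tie & (slope > 0)] = TrendCategory.INCREASE
    cat[tie & (slope < 0)] = TrendCategory.DECREASE
    return cat


def trend_grid(stack: np.ndarray, min_years: int = 3) -> TrendGrid:
    """Theil-Sen + Mann-Kendall + OLS per pixel of an annual stack.

    ``stack`` has shape (n_years, n_rows, n_cols).  Pixels with fewer than
    ``min_years`` finite values are flagged invalid (NaN statistics).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must have shape (n_years, n_rows, n_cols)")
    n_years, nr, nc = stack.shape
    if n_years < 3:
        raise InsufficientDataError("trend grid needs >= 3 years")
    x = stack.reshape(n_years, -1)
    finite_count = np.isfinite(x).sum(axis=0)
    valid = finite_count >= max(min_years, 3)
    complete = finite_count == n_years

    slope = np.full(x.shape[1], np.nan)
    z = np.full(x.shape[1], np.nan)
    ols = np.full(x.shape[1], np.nan)
    if complete.any():
        xc = x[:, complete]
        slope[complete] = _ts_slope_grid(xc)
        z[complete] = _mk_z_grid(xc)
        ols[complete] = _ols_slope_grid(xc)
    # gappy-but-valid pixels: scalar path
    for p in np.flatnonzero(valid & ~complete):
        slope[p] = theil_sen(x[:, p])
        z[p] = mann_kendall(x[:, p]).z
        ols[p] = linear_trend(x[:, p])

    cat = np.zeros(x.shape[1], dtype=np.int8)
    cat[valid] = classify_trend_grid(z[valid], slope[valid])
    shape = (nr, nc)
    return TrendGrid(
        slope=slope.reshape(shape),
        z=z.reshape(shape),
        ols_slope=ols.reshape(shape),
        category=cat.reshape(shape),
        valid=valid.reshape(shape),
    )
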