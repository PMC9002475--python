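"""Standardized Precipitation-Evapotranspiration Index (SPEI).

The climatic water balance D = PRE - PET is accumulated over a timescale of
k months (backward-looking window ending in the indexed month), a
three-parameter log-logistic distribution is fitted to each calendar
month's accumulated values via unbiased probability-weighted moments, and
the fitted cumulative probabilities are mapped to standard-normal units.
Values below -1 denote drought.

Also provides Hargreaves potential evapotranspiration from air temperature
and standard solar-geometry extraterrestrial radiation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
from scipy.special import gamma as _gamma
from scipy.stats import norm as _norm

from .grids import DAYS_IN_MONTH, DimensionError, MonthlyGrid

DEFAULT_SCALES: tuple[int, ...] = (1, 3, 6, 12)

#: SPEI below this value is classified as drought (one SD below normal).
DROUGHT_THRESHOLD: float = -1.0

#: Minimum finite calibration samples per calendar month for a valid fit.
MIN_CALIBRATION_SAMPLES: int = 10


class ScaleError(ValueError):
    """Accumulation scale incompatible with the series length."""


class FitError(ValueError):
    """Log-logistic parameter estimation failed (e.g. degenerate sample)."""


def is_drought(spei: np.ndarray | float) -> np.ndarray | bool:
    """Drought indicator: SPEI strictly below -1."""
    return np.asarray(spei) < DROUGHT_THRESHOLD if np.ndim(spei) else spei < DROUGHT_THRESHOLD


# --------------------------------------------------------------------------
# accumulation
# --------------------------------------------------------------------------

def accumulate(d: np.ndarray, k: int) -> np.ndarray:
    """k-month backward cumulative sum along the first axis.

    Element t (t >= k-1) is ``sum(d[t-k+1 .. t])``; the first k-1 elements
    are NaN (undefined: the window extends before the record).  NaNs inside
    a window propagate, so partially missing pixels stay flagged.
    """
    d = np.asarray(d, dtype=float)
    if k < 1:
        raise ScaleError(f"scale must be >= 1, got {k}")
    if d.shape[0] < k:
        raise ScaleError(f"scale {k} exceeds series length {d.shape[0]}")
    if k == 1:
        return d.copy()
    win = np.lib.stride_tricks.sliding_window_view(d, k, axis=0)
    acc = np.full(d.shape, np.nan)
    acc[k - 1:] = win.sum(axis=-1)
    return acc


# --------------------------------------------------------------------------
# probability-weighted moments / log-logistic fit
# --------------------------------------------------------------------------

def _pwm_unbiased(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Unbiased PWMs a_s = E[X (1-F)^s], s = 0, 1, 2, column-wise.

    ``samples`` has shape (n_obs, n_cols); NaN entries are ignored.
    Returns (a0, a1, a2, n) with shape (n_cols,).
    """
    x = np.sort(samples, axis=0)  # NaN sort to the end
    n = np.sum(np.isfinite(samples), axis=0).astype(float)
    i = np.arange(x.shape[0], dtype=float)[:, None]  # 0-based rank
    # ascending rank j = i+1; weight numerators (n-j) and (n-j)(n-j-1)
    nmj = n[None, :] - i - 1.0
    x0 = np.where(np.isfinite(x), x, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a0 = np.nansum(x0 * np.isfinite(x), axis=0) / n
        a1 = np.sum(x0 * np.clip(nmj, 0.0, None), axis=0) / (n * (n - 1.0))
        a2 = np.sum(x0 * np.clip(nmj, 0.0, None) * np.clip(nmj - 1.0, 0.0, None), axis=0) / (
            n * (n - 1.0) * (n - 2.0)
        )
    return a0, a1, a2, n


@dataclass(frozen=True)
class LogLogisticParams:
    """Three-parameter log-logistic: CDF(x) = [1 + (scale/(x-origin))^shape]^-1.

    Where ``reflected`` is set, the parameters describe the distribution of
    the NEGATED sample and probabilities are evaluated as
    ``1 - CDF(-x)``: the three-parameter log-logistic is right-skewed, so
    near-symmetric or left-skewed calibration samples (which arise for
    accumulated water balances) are standardized through their mirror
    image instead of failing.
    """

    shape: float | np.ndarray
    scale: float | np.ndarray
    origin: float | np.ndarray
    reflected: bool | np.ndarray = False


def fit_loglogistic(samples: np.ndarray) -> LogLogisticParams:
    """Fit a three-parameter log-logistic by unbiased probability-weighted moments.

    ``samples`` may be 1-D (one calibration sample) or 2-D (n_obs, n_cols)
    for vectorized per-column fits.  1-D degenerate input raises
    :class:`FitError`; in 2-D, invalid columns yield NaN parameters.
    """
    arr = np.asarray(samples, dtype=float)
    one_d = arr.ndim == 1
    if one_d:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError("samples must be 1-D or 2-D")

    def _moments(x: np.ndarray):
        a0, a1, a2, n = _pwm_unbiased(x)
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = 6.0 * a1 - a0 - 6.0 * a2
            shape = (2.0 * a1 - a0) / denom
            g = _gamma(1.0 + 1.0 / shape) * _gamma(1.0 - 1.0 / shape)
            scale = (a0 - 2.0 * a1) * shape / g
            origin = a0 - scale * g
        valid = (
            np.isfinite(shape) & (shape > 1.0)
            & np.isfinite(scale) & (scale > 0)
            & np.isfinite(origin)
        )
        return shape, scale, origin, n, valid

    import warnings as _warnings
    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        xmin = np.nanmin(arr, axis=0)
        xmax = np.nanmax(arr, axis=0)
        spread = xmax - xmin
    s1, sc1, o1, n, ok1 = _moments(arr)
    # left-skewed/near-symmetric samples: fit the mirror image instead
    s2, sc2, o2, _, ok2 = _moments(-arr)
    # the fitted support must cover the calibration sample, else the lowest
    # (highest, mirrored) observation would map to probability ~0 (~1)
    ok1 = ok1 & (o1 < xmin)
    ok2 = ok2 & (o2 < -xmax)
    usable = (n >= MIN_CALIBRATION_SAMPLES) & (spread > 0)
    use1 = usable & ok1
    use2 = usable & ~ok1 & ok2
    ok = use1 | use2
    shape = np.where(use1, s1, np.where(use2, s2, np.nan))
    scale = np.where(use1, sc1, np.where(use2, sc2, np.nan))
    origin = np.where(use1, o1, np.where(use2, o2, np.nan))

    if one_d:
        if not ok[0]:
            n0 = int(n[0])
            if n0 < MIN_CALIBRATION_SAMPLES:
                raise FitError(
                    f"need >= {MIN_CALIBRATION_SAMPLES} finite samples, got {n0}"
                )
            if spread[0] <= 0:
                raise FitError("degenerate (constant) sample: log-logistic fit undefined")
            raise FitError("log-logistic moment estimates invalid for this sample")
        return LogLogisticParams(float(shape[0]), float(scale[0]), float(origin[0]),
                                 bool(use2[0]))
    return LogLogisticParams(shape, scale, origin, use2)


def _cdf3(x: np.ndarray, shape, scale, origin) -> np.ndarray:
    eps = 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - origin) / scale
        f = 1.0 / (1.0 + np.power(np.clip(z, eps, None), -shape))
        # x at/below the origin -> minimum representable probability
        f = np.where(z <= 0, eps, f)
        # NaN input or NaN (invalid-fit) parameters stay missing
        f = np.where(np.isfinite(z), f, np.nan)
    return np.clip(f, eps, 1.0 - eps)


def loglogistic_cdf(x: np.ndarray, params: LogLogisticParams) -> np.ndarray:
    """CDF of the fitted three-parameter log-logistic, clipped away from 0/1.

    Mirror-fitted parameters (``params.reflected``) evaluate as
    ``1 - CDF(-x)``; the result is monotone increasing in x either way.
    """
    x = np.asarray(x, dtype=float)
    reflected = np.asarray(params.reflected)
    direct = _cdf3(x, params.shape, params.scale, params.origin)
    if not reflected.any():
        return direct
    mirror = 1.0 - _cdf3(-x, params.shape, params.scale, params.origin)
    return np.where(reflected, mirror, direct)


# --------------------------------------------------------------------------
# normal quantile and the SPEI transform
# --------------------------------------------------------------------------

_C0, _C1, _C2 = 2.515517, 0.802853, 0.010328
_D1, _D2, _D3 = 1.432788, 0.189269, 0.001308


def normal_quantile_rational(p: np.ndarray) -> np.ndarray:
    """Standard-normal quantile via the classic rational approximation.

    Max absolute error about 4.5e-4; this is the quantile used by the
    canonical SPEI implementation.  A high-precision alternative is
    available through ``method='exact'`` in :func:`spei_transform`.
    """
    p = np.asarray(p, dtype=float)
    q = np.where(p <= 0.5, p, 1.0 - p)
    q = np.clip(q, 1e-300, 0.5)
    w = np.sqrt(-2.0 * np.log(q))
    t = w - (_C0 + _C1 * w + _C2 * w**2) / (1.0 + _D1 * w + _D2 * w**2 + _D3 * w**3)
    return np.where(p <= 0.5, -t, t)


#: SPEI clamp, the standard-normal quantile at p = 0.001: beyond this the
#: fitted tail is not resolvable from a ~29-year calibration sample.
SPEI_CLAMP: float = 3.09


def spei_transform(
    x: np.ndarray, params: LogLogisticParams, method: str = "rational"
) -> np.ndarray:
    """Map accumulated water-balance values to SPEI (standard-normal units).

    Values at or below the distribution origin are mapped through the
    minimum representable probability rather than NaN, so record-dry
    months remain comparable; the index is clamped to +/-3.09 (p = 0.001),
    the conventional bound for standardized drought indices.  The mapping
    is strictly increasing in the input between the clamp bounds.
    """
    f = loglogistic_cdf(x, params)
    if method == "rational":
        z = normal_quantile_rational(f)
    elif method == "exact":
        z = _norm.ppf(f)
    else:
        raise ValueError(f"unknown quantile method {method!r}")
    return np.clip(z, -SPEI_CLAMP, SPEI_CLAMP)


# --------------------------------------------------------------------------
# gridded SPEI
# --------------------------------------------------------------------------

def spei_series(d: np.ndarray, scales: Sequence[int] = DEFAULT_SCALES,
                method: str = "rational") -> Dict[int, np.ndarray]:
    """SPEI of one monthly water-balance series (length multiple of 12).

    Calibration is per calendar month over the full record.  Returns a dict
    scale -> series of the same length (first k-1 values NaN).
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 1 or d.size % 12:
        raise DimensionError("series length must be a positive multiple of 12")
    out = {}
    for k in scales:
        acc = accumulate(d, k)
        z = np.full_like(acc, np.nan)
        for m in range(12):
            vals = acc[m::12]
            finite = np.isfinite(vals)
            if finite.sum() < MIN_CALIBRATION_SAMPLES:
                continue
            try:
                params = fit_loglogistic(vals[finite])
            except FitError:
                continue
            z[m::12] = np.where(finite, spei_transform(vals, params, method), np.nan)
        out[k] = z
    return out


def spei_grid(
    pre: MonthlyGrid,
    pet: MonthlyGrid,
    scales: Sequence[int] = DEFAULT_SCALES,
    method: str = "rational",
) -> Dict[int, MonthlyGrid]:
    """Multi-scale SPEI per pixel from gridded monthly PRE and PET.

    Per pixel, per scale and per calendar month: accumulate the water
    balance, fit the log-logistic by PWM across years, and transform to
    standard-normal units.  Pixels/months with fewer than
    ``MIN_CALIBRATION_SAMPLES`` defined calibration values (or degenerate
    samples) stay missing.
    """
    pre.require_same_layout(pet)
    d = pre.flatten_time() - pet.flatten_time()  # (T, npix)
    n_years = pre.n_years
    npix = d.shape[1]
    result: Dict[int, MonthlyGrid] = {}
    for k in scales:
        acc = accumulate(d, k)
        z = np.full_like(acc, np.nan)
        for m in range(12):
            vals = acc[m::12]  # (n_years_m, npix)
            params = fit_loglogistic(vals)
            z[m::12] = spei_transform(vals, params, method)
        data = z.reshape(n_years, 12, *pre.grid_shape)
        result[k] = MonthlyGrid(
            data, start_year=pre.start_year, units="sd", name=f"spei_{k}"
        )
    return result


# --------------------------------------------------------------------------
# Hargreaves PET
# --------------------------------------------------------------------------

_GSC = 0.0820  # solar constant, MJ m-2 min-1
_MID_MONTH_DOY = np.cumsum((0,) + DAYS_IN_MONTH[:-1]) + np.asarray(DAYS_IN_MONTH) / 2.0


def extraterrestrial_radiation(latitude: float | np.ndarray, month: int) -> np.ndarray:
    """Extraterrestrial radiation Ra in evaporation-equivalent mm/day.

    Standard solar-geometry formulas (inverse relative Earth-Sun distance,
    solar declination, sunset hour angle) evaluated at the mid-month day of
    a fixed 365-day calendar; MJ m-2 day-1 converted at 0.408 mm/MJ.
    """
    if not 1 <= month <= 12:
        raise ValueError(f"month must be 1..12, got {month}")
    phi = np.deg2rad(np.asarray(latitude, dtype=float))
    j = _MID_MONTH_DOY[month - 1]
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * j / 365.0)
    delta = 0.409 * np.sin(2.0 * np.pi * j / 365.0 - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0))
    ra_mj = (24.0 * 60.0 / np.pi) * _GSC * dr * (
        ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws)
    )
    return 0.408 * ra_mj


def hargreaves_pet(
    tmean: np.ndarray,
    tmin: np.ndarray,
    tmax: np.ndarray,
    latitude: float | np.ndarray,
    month: int,
) -> np.ndarray:
    """Monthly Hargreaves PET (mm/month) from air temperature.

    PET/day = 0.0023 * Ra * (tmean + 17.8) * sqrt(tmax - tmin), clamped at
    zero, times the days in the month.
    """
    tmean = np.asarray(tmean, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmax < tmin):
        raise ValueError("tmax must be >= tmin everywhere")
    ra = extraterrestrial_radiation(latitude, month)
    per_day = 0.0023 * ra * (tmean + 17.8) * np.sqrt(tmax - tmin)
    return np.clip(per_day, 0.0, None) * DAYS_IN_MONTH[month - 1]
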