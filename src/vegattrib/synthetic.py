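"""Seeded synthetic gridded climate + NDVI scenes with known ground truth.

Monthly temperature, precipitation and potential evapotranspiration carry a
mean, a summer-peaking sinusoidal seasonal cycle, an optional linear trend
and Gaussian interannual noise.  NDVI is built so its annual growing-season
mean obeys the linear climate model

    NDVI_gs(year) = base + a * PRE_gs + b * PET_gs + h * year + eps,

with h an implanted per-region human-activity trend and eps ~ N(0,
noise_sd^2); the annual value is spread over April-October with a fixed
triangular profile peaking in July.  The per-pixel truth table records the
coefficients, the implanted trend, the realized climate-driven slope and
the attribution scenario each pixel should land in, so every downstream
stage has recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping

import numpy as np
import pandas as pd

from .grids import GROWING_SEASON, DimensionError, MonthlyGrid
from . import restrend as _restrend
from . import spei as _spei
from . import trends as _trends


class ConfigurationError(ValueError):
    """Invalid synthetic-scene configuration."""


#: Triangular within-season NDVI weights for Apr..Oct, peaking in July and
#: normalized to mean 1 so the growing-season mean stays analytically exact.
#: The raised baseline keeps the July peak ~1.4x the seasonal mean, typical
#: of temperate phenology, and keeps peak NDVI away from the [-1, 1] clip.
SEASON_PROFILE = np.array([3.0, 4.0, 5.0, 6.0, 5.0, 4.0, 3.0])
SEASON_PROFILE = SEASON_PROFILE / SEASON_PROFILE.mean()

#: NDVI in the dormant months, as a fraction of the growing-season mean.
OFF_SEASON_FRACTION = 0.3


@dataclass
class RegionLayout:
    """Block layout of the categorical masks.

    Land cover: a (rows x cols) grid of rectangular blocks, classes
    numbered 1.. in row-major order.  Climate region: horizontal bands.
    """

    landcover_blocks: tuple[int, int] = (2, 2)
    climregion_bands: int = 3

    def validate(self, n_rows: int, n_cols: int) -> None:
        br, bc = self.landcover_blocks
        if br < 1 or bc < 1 or self.climregion_bands < 1:
            raise ConfigurationError("region layout must have >= 1 block per axis")
        if br > n_rows or bc > n_cols or self.climregion_bands > n_rows:
            raise ConfigurationError(
                f"layout {self!r} does not cover a {n_rows}x{n_cols} grid"
            )


@dataclass
class SyntheticConfig:
    """Study conditions of a synthetic scene.

    Defaults describe a temperate monsoon-like grid: ~29 years of monthly
    data, moist summers, and an NDVI linearly coupled to growing-season
    precipitation (positively) and evaporative demand (negatively), with
    block-wise implanted human trends of +/-0.002 NDVI/year.  Climate is
    stationary by default (``pre_trend = pet_trend = 0``): residual-trend
    attribution assumes climate variability is trend-free, and a
    deterministic climate trend confounds the implanted human signal (see
    the methods note).  Paper-style trended climate is opted into via
    :func:`trended_climate_config`.
    """

    n_rows: int = 50
    n_cols: int = 50
    n_years: int = 29
    start_year: int = 1990
    seed: int = 0

    # precipitation, mm/month
    pre_mean: float = 80.0
    pre_seasonal_amp: float = 40.0
    pre_trend: float = 0.0          # mm/year, applied to every month
    pre_noise_sd: float = 25.0

    # temperature, degC
    tem_mean: float = 6.0
    tem_seasonal_amp: float = 18.0
    tem_trend: float = 0.0          # degC/year
    tem_noise_sd: float = 1.0

    # potential evapotranspiration, mm/month
    pet_mean: float = 60.0
    pet_seasonal_amp: float = 40.0
    pet_trend: float = 0.0          # mm/year
    pet_noise_sd: float = 12.0
    pet_from_temperature: bool = False
    latitude: float = 45.0          # degrees, used by the Hargreaves option
    diurnal_range: float = 10.0     # degC, tmax - tmin for the Hargreaves option

    # NDVI model
    ndvi_base: float = 0.10
    coef_pre: float = 0.004         # a, NDVI per mm
    coef_pet: float = -0.0015       # b, NDVI per mm
    noise_sd: float = 0.02          # eps SD, NDVI units
    human_trend_map: Dict[int, float] = field(
        default_factory=lambda: {1: 0.002, 2: -0.002, 3: 0.002, 4: -0.002}
    )

    region_layout: RegionLayout = field(default_factory=RegionLayout)

    def validate(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigurationError("grid dimensions must be positive")
        if self.n_years < 10:
            raise ConfigurationError("n_years must be >= 10")
        if self.noise_sd < 0 or self.pre_noise_sd < 0 or self.tem_noise_sd < 0 \
                or self.pet_noise_sd < 0:
            raise ConfigurationError("noise SDs must be >= 0")
        if self.pre_seasonal_amp < 0 or self.tem_seasonal_amp < 0 \
                or self.pet_seasonal_amp < 0:
            raise ConfigurationError("seasonal amplitudes must be >= 0")
        self.region_layout.validate(self.n_rows, self.n_cols)


def trended_climate_config(**overrides) -> SyntheticConfig:
    """Config with the drying/warming climate trends of a NE-China-like study
    window: PRE -1.25 mm/yr, PET +1.17 mm/yr, TEM +0.02 degC/yr."""
    cfg = SyntheticConfig(pre_trend=-1.25, pet_trend=1.17, tem_trend=0.02)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@dataclass
class SyntheticScene:
    """A generated scene plus its per-pixel ground truth."""

    tem: MonthlyGrid
    pre: MonthlyGrid
    pet: MonthlyGrid
    ndvi: MonthlyGrid
    landcover: np.ndarray
    climregion: np.ndarray
    truth: pd.DataFrame
    config: SyntheticConfig


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def _seasonal(amp: float) -> np.ndarray:
    """Summer-peaking cosine cycle over months 1..12 (peak in July)."""
    m = np.arange(1, 13)
    return amp * np.cos(2.0 * np.pi * (m - 7) / 12.0)


def _rng_for(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per variable group
    return np.random.default_rng([int(config.seed), stream])


def _build_field(mean: float, amp: float, trend: float, noise_sd: float,
                 config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    yrs = np.arange(config.n_years, dtype=float)
    base = mean + _seasonal(amp)[None, :] + trend * yrs[:, None]
    data = base[:, :, None, None] + np.zeros((1, 1, config.n_rows, config.n_cols))
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return data


def generate_climate(config: SyntheticConfig) -> tuple[MonthlyGrid, MonthlyGrid, MonthlyGrid]:
    """Monthly TEM, PRE and PET grids (seeded, deterministic for a config).

    PRE is truncated at 0 after noise; truncated cells read exactly 0.0 so
    downstream truth bookkeeping can flag them.  PET comes either from its
    own sinusoid or from Hargreaves evaluated on the generated temperature.
    """
    config.validate()
    tem = _build_field(config.tem_mean, config.tem_seasonal_amp, config.tem_trend,
                       config.tem_noise_sd, config, _rng_for(config, 0))
    pre = _build_field(config.pre_mean, config.pre_seasonal_amp, config.pre_trend,
                       config.pre_noise_sd, config, _rng_for(config, 1))
    pre = np.clip(pre, 0.0, None)
    if config.pet_from_temperature:
        half = config.diurnal_range / 2.0
        pet = np.empty_like(tem)
        for m in range(12):
            pet[:, m] = _spei.hargreaves_pet(
                tem[:, m], tem[:, m] - half, tem[:, m] + half,
                config.latitude, m + 1,
            )
    else:
        pet = _build_field(config.pet_mean, config.pet_seasonal_amp, config.pet_trend,
                           config.pet_noise_sd, config, _rng_for(config, 2))
        pet = np.clip(pet, 0.0, None)
    sy = config.start_year
    return (
        MonthlyGrid(tem, sy, "degC", "tem"),
        MonthlyGrid(pre, sy, "mm", "pre"),
        MonthlyGrid(pet, sy, "mm", "pet"),
    )


def generate_masks(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Categorical land-cover (blocks) and climate-region (bands) grids."""
    config.region_layout.validate(config.n_rows, config.n_cols)
    br, bc = config.region_layout.landcover_blocks
    row_ids = np.repeat(np.arange(br), [len(a) for a in np.array_split(range(config.n_rows), br)])
    col_ids = np.repeat(np.arange(bc), [len(a) for a in np.array_split(range(config.n_cols), bc)])
    landcover = (row_ids[:, None] * bc + col_ids[None, :] + 1).astype(np.int32)
    nb = config.region_layout.climregion_bands
    band_ids = np.repeat(np.arange(nb), [len(a) for a in np.array_split(range(config.n_rows), nb)])
    climregion = np.broadcast_to((band_ids + 1)[:, None], (config.n_rows, config.n_cols))
    return landcover, np.ascontiguousarray(climregion, dtype=np.int32)


def human_trend_grid(config: SyntheticConfig, landcover: np.ndarray) -> np.ndarray:
    """Per-pixel implanted human trend h (NDVI/year) from the class map."""
    h = np.zeros(landcover.shape, dtype=float)
    for cls, val in config.human_trend_map.items():
        h[landcover == cls] = val
    return h


def generate_ndvi(pre: MonthlyGrid, pet: MonthlyGrid, config: SyntheticConfig) -> MonthlyGrid:
    """NDVI grid whose growing-season annual mean follows the linear model.

    The Apr-Oct mean of each pixel-year equals
    ``base + a*PRE_gs + b*PET_gs + h*year + eps`` exactly (before clipping);
    months within the season carry the fixed triangular profile, dormant
    months a small fraction of the seasonal mean.  Values clip to [-1, 1].
    """
    pre.require_same_layout(pet)
    if pre.grid_shape != (config.n_rows, config.n_cols):
        raise DimensionError("climate grids do not match the configured grid size")
    landcover, _ = generate_masks(config)
    h = human_trend_grid(config, landcover)
    rng = _rng_for(config, 3)

    pre_gs = pre.growing_season_mean()          # (Y, r, c)
    pet_gs = pet.growing_season_mean()
    yrs = np.arange(config.n_years, dtype=float)[:, None, None]
    gs_mean = (config.ndvi_base + config.coef_pre * pre_gs
               + config.coef_pet * pet_gs + h[None] * yrs)
    if config.noise_sd > 0:
        gs_mean = gs_mean + rng.normal(0.0, config.noise_sd, size=gs_mean.shape)

    data = np.empty((config.n_years, 12, config.n_rows, config.n_cols))
    data[:] = (OFF_SEASON_FRACTION * gs_mean)[:, None]
    for wi, m in enumerate(GROWING_SEASON):
        data[:, m - 1] = SEASON_PROFILE[wi] * gs_mean
    data = np.clip(data, -1.0, 1.0)
    return MonthlyGrid(data, config.start_year, "", "ndvi")


def generate_spei_coupled_ndvi(
    pre: MonthlyGrid,
    pet: MonthlyGrid,
    config: SyntheticConfig,
    scale: int = 12,
    coupling: float = 0.05,
    base: float = 0.3,
) -> MonthlyGrid:
    """NDVI driven directly by the SPEI at one timescale.

    Monthly NDVI = base + coupling * SPEI_scale + noise wherever the SPEI
    is defined (base + noise elsewhere).  Used to probe the correlation
    stage: the strongest NDVI-SPEI coupling sits, by construction, at the
    chosen timescale with a positive sign.
    """
    spei_k = _spei.spei_grid(pre, pet, scales=(scale,))[scale]
    rng = _rng_for(config, 4)
    signal = np.where(np.isfinite(spei_k.data), coupling * spei_k.data, 0.0)
    data = base + signal + rng.normal(0.0, config.noise_sd, size=spei_k.data.shape)
    data = np.clip(data, -1.0, 1.0)
    return MonthlyGrid(data, config.start_year, "", "ndvi")


# --------------------------------------------------------------------------
# scene assembly with truth bookkeeping
# --------------------------------------------------------------------------

def _truth_table(config: SyntheticConfig, pre: MonthlyGrid, pet: MonthlyGrid,
                 ndvi: MonthlyGrid, landcover: np.ndarray,
                 climregion: np.ndarray) -> pd.DataFrame:
    h = human_trend_grid(config, landcover)
    pre_gs = pre.growing_season_mean()
    pet_gs = pet.growing_season_mean()
    # realized climate-driven NDVI component (noiseless)
    climate_part = config.coef_pre * pre_gs + config.coef_pet * pet_gs
    yrs = np.arange(config.n_years, dtype=float)
    tc = yrs - yrs.mean()
    flat = climate_part.reshape(config.n_years, -1)
    slope_pre_true = (tc @ (flat - flat.mean(axis=0)) / np.sum(tc * tc))
    slope_res_true = h.reshape(-1)
    slope_obs_true = slope_pre_true + slope_res_true

    scenario, _, _ = _restrend.attribute(slope_obs_true, slope_pre_true, slope_res_true)

    # strict-mode truth: the same rules with the trend-existence gate applied
    # to the noiseless components (Mann-Kendall on the climate part; the
    # human part h*t is exactly monotone, so its score is +/-Z(n) or 0)
    z_pre_true = _trends.trend_grid(climate_part).z.reshape(-1)
    z_mono = _trends.mann_kendall(np.arange(config.n_years, dtype=float)).z
    z_res_true = np.sign(slope_res_true) * z_mono
    scenario_strict, _, _ = _restrend.attribute(
        slope_obs_true, slope_pre_true, slope_res_true,
        z_pre=z_pre_true, z_res=z_res_true, strict=True,
    )

    gs_idx = [m - 1 for m in GROWING_SEASON]
    truncated_gs = (pre.data[:, gs_idx] == 0.0).any(axis=(0, 1)).reshape(-1)
    clipped = (np.abs(ndvi.data) >= 1.0).any(axis=(0, 1)).reshape(-1)

    rows, cols = np.indices((config.n_rows, config.n_cols))
    return pd.DataFrame({
        "row": rows.reshape(-1),
        "col": cols.reshape(-1),
        "landcover": landcover.reshape(-1),
        "climregion": climregion.reshape(-1),
        "a": config.coef_pre,
        "b": config.coef_pet,
        "h": slope_res_true,
        "slope_pre_true": slope_pre_true,
        "slope_res_true": slope_res_true,
        "slope_obs_true": slope_obs_true,
        "scenario": scenario.reshape(-1),
        "scenario_strict": scenario_strict.reshape(-1),
        "z_pre_true": z_pre_true,
        "z_res_true": z_res_true,
        "truncated_gs": truncated_gs,
        "clipped": clipped,
    })


def generate_scene(config: SyntheticConfig) -> SyntheticScene:
    """Generate a full scene (climate, NDVI, masks, truth); bit-reproducible
    for identical configs."""
    config.validate()
    tem, pre, pet = generate_climate(config)
    landcover, climregion = generate_masks(config)
    ndvi = generate_ndvi(pre, pet, config)
    truth = _truth_table(config, pre, pet, ndvi, landcover, climregion)
    return SyntheticScene(tem, pre, pet, ndvi, landcover, climregion, truth, config)
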