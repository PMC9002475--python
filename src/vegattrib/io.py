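"""Readers/writers and pipeline configuration.

Monthly grids round-trip through NetCDF (classic format, via xarray's
scipy backend) or plain multi-page TIFF stacks (one page per month, via
tifffile, calendar/units metadata in the image description).  Pipeline
configuration lives in YAML.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import xarray as xr
import yaml

from .grids import GROWING_SEASON, DimensionError, MonthlyGrid


class FormatError(ValueError):
    """Unrecognized or malformed raster file."""


# --------------------------------------------------------------------------
# NetCDF
# --------------------------------------------------------------------------

def write_netcdf(grid: MonthlyGrid, path: str | Path) -> None:
    da = grid.to_dataarray()
    da.to_dataset(name=da.name).to_netcdf(path, engine="scipy")


def read_netcdf(path: str | Path) -> MonthlyGrid:
    try:
        ds = xr.open_dataset(path, engine="scipy")
    except Exception as exc:  # pragma: no cover - message path
        raise FormatError(f"cannot read NetCDF stack {path}: {exc}") from exc
    with ds:
        names = [n for n in ds.data_vars if ds[n].ndim == 4]
        if not names:
            raise FormatError(f"{path}: no (year, month, y, x) variable found")
        da = ds[names[0]].load()
    if tuple(da.dims) != ("year", "month", "y", "x"):
        raise FormatError(
            f"{path}: expected axes (year, month, y, x), got {tuple(da.dims)}"
        )
    if da.sizes["month"] != 12:
        raise FormatError(f"{path}: month axis has length {da.sizes['month']}, not 12")
    return MonthlyGrid.from_dataarray(da)


# --------------------------------------------------------------------------
# TIFF stacks (one page per month, year-major order)
# --------------------------------------------------------------------------

def write_tiff(grid: MonthlyGrid, path: str | Path) -> None:
    meta = {"start_year": grid.start_year, "units": grid.units,
            "name": grid.name, "n_years": grid.n_years}
    pages = grid.data.reshape(-1, *grid.grid_shape).astype(np.float32)
    tifffile.imwrite(path, pages, description=json.dumps(meta))


def read_tiff(path: str | Path) -> MonthlyGrid:
    try:
        with tifffile.TiffFile(path) as tif:
            pages = tif.asarray()
            desc = tif.pages[0].description or "{}"
    except Exception as exc:
        raise FormatError(f"cannot read TIFF stack {path}: {exc}") from exc
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    if pages.ndim != 3 or pages.shape[0] % 12:
        raise FormatError(
            f"{path}: page axis must hold n_years*12 monthly bands, got {pages.shape}"
        )
    data = np.asarray(pages, dtype=float).reshape(-1, 12, *pages.shape[1:])
    return MonthlyGrid(data, start_year=int(meta.get("start_year", 1990)),
                       units=str(meta.get("units", "")), name=str(meta.get("name", "")))


def read_stack(path: str | Path) -> MonthlyGrid:
    """Load a monthly grid from NetCDF (.nc) or TIFF (.tif/.tiff)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".nc":
        return read_netcdf(path)
    if suffix in (".tif", ".tiff"):
        return read_tiff(path)
    raise FormatError(f"unrecognized stack format: {path.suffix!r}")


def write_stack(grid: MonthlyGrid, path: str | Path) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".nc":
        write_netcdf(grid, path)
    elif suffix in (".tif", ".tiff"):
        write_tiff(grid, path)
    else:
        raise FormatError(f"unrecognized stack format: {path.suffix!r}")


# --------------------------------------------------------------------------
# pipeline configuration
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; defaults mirror the analysis choices
    (Apr-Oct growing season, SPEI scales 1/3/6/12, 1.96 significance,
    5-year smoothing window)."""

    output_dir: str = "vegattrib_out"
    seed: int = 0
    months: tuple[int, ...] = GROWING_SEASON
    scales: tuple[int, ...] = (1, 3, 6, 12)
    significance_z: float = 1.96
    moving_average_window: int = 5
    strict_attribution: bool = False
    grid_rows: int = 50
    grid_cols: int = 50
    n_years: int = 29

    def validate(self) -> None:
        months = sorted(self.months)
        if not months or any(m < 1 or m > 12 for m in months):
            raise ValueError("months must lie in 1..12")
        if months != list(range(months[0], months[-1] + 1)):
            raise ValueError("months must be contiguous")
        if list(self.scales) != sorted(set(self.scales)):
            raise ValueError("scales must be sorted ascending, unique")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["months"] = list(self.months)
        d["scales"] = list(self.scales)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "months" in d:
            d["months"] = tuple(d["months"])
        if "scales" in d:
            d["scales"] = tuple(d["scales"])
        cfg = cls(**d)
        cfg.validate()
        return cfg
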