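"""Container for gridded monthly time series.

Every physical variable in the pipeline (temperature, precipitation,
potential evapotranspiration, NDVI, SPEI) travels as a :class:`MonthlyGrid`:
a dense ``(n_years, 12, n_rows, n_cols)`` float array with NaN marking
missing data, plus minimal calendar/units metadata.  Grids are abstract
(equal-area pixels, no CRS); georeferencing is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import xarray as xr

#: April-October, the months over which vegetation statistics are computed.
GROWING_SEASON: tuple[int, ...] = (4, 5, 6, 7, 8, 9, 10)

#: Day counts of a fixed 365-day calendar.
DAYS_IN_MONTH: tuple[int, ...] = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)


class DimensionError(ValueError):
    """Raised when grid shapes or axes do not line up."""


@dataclass
class MonthlyGrid:
    """A (year, month, row, col) stack of one physical variable.

    Parameters
    ----------
    data
        Array of shape ``(n_years, 12, n_rows, n_cols)``; NaN = missing.
    start_year
        Calendar year of index 0 along the year axis.
    units, name
        Free-text metadata carried through I/O round trips.
    """

    data: np.ndarray
    start_year: int = 1990
    units: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[1] != 12:
            raise DimensionError(
                f"MonthlyGrid data must have shape (n_years, 12, n_rows, n_cols); "
                f"got {self.data.shape}"
            )

    # ------------------------------------------------------------------ shape
    @property
    def n_years(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    @property
    def years(self) -> np.ndarray:
        return self.start_year + np.arange(self.n_years)

    def require_same_layout(self, other: "MonthlyGrid") -> None:
        if self.data.shape != other.data.shape:
            raise DimensionError(
                f"grid shape mismatch: {self.data.shape} vs {other.data.shape}"
            )
        if self.start_year != other.start_year:
            raise DimensionError(
                f"calendar mismatch: start years {self.start_year} vs {other.start_year}"
            )

    # ------------------------------------------------------------- selections
    def annual_mean(self, months: Sequence[int] | None = None) -> np.ndarray:
        """Mean over the given calendar months, per year and pixel.

        Returns shape ``(n_years, n_rows, n_cols)``.  A year/pixel cell is
        NaN only if every selected month is missing.
        """
        if months is None:
            months = tuple(range(1, 13))
        idx = [m - 1 for m in months]
        if any(i < 0 or i > 11 for i in idx):
            raise ValueError(f"months must lie in 1..12, got {months}")
        sel = self.data[:, idx, :, :]
        with np.errstate(invalid="ignore"):
            return np.nanmean(sel, axis=1)

    def growing_season_mean(self) -> np.ndarray:
        """April-October mean, per year and pixel."""
        return self.annual_mean(GROWING_SEASON)

    def flatten_time(self) -> np.ndarray:
        """View as ``(n_years*12, n_rows*n_cols)`` in calendar order."""
        y, m, r, c = self.data.shape
        return self.data.reshape(y * m, r * c)

    def pixel_series(self, row: int, col: int) -> np.ndarray:
        """Flat monthly series for one pixel, length ``n_years*12``."""
        return self.data[:, :, row, col].reshape(-1)

    def copy_with(self, data: np.ndarray, **meta) -> "MonthlyGrid":
        out = replace(self, data=np.asarray(data, dtype=float))
        for k, v in meta.items():
            setattr(out, k, v)
        return out

    # ------------------------------------------------------------------- I/O
    def to_dataarray(self) -> xr.DataArray:
        da = xr.DataArray(
            self.data,
            dims=("year", "month", "y", "x"),
            coords={"year": self.years, "month": np.arange(1, 13)},
            name=self.name or "variable",
            attrs={"units": self.units},
        )
        return da

    @classmethod
    def from_dataarray(cls, da: xr.DataArray) -> "MonthlyGrid":
        if tuple(da.dims) != ("year", "month", "y", "x"):
            raise DimensionError(
                f"expected dims (year, month, y, x), got {tuple(da.dims)}"
            )
        start_year = int(da.coords["year"].values[0]) if "year" in da.coords else 1990
        return cls(
            data=np.asarray(da.values, dtype=float),
            start_year=start_year,
            units=str(da.attrs.get("units", "")),
            name=str(da.name or ""),
        )


def month_of_index(t: np.ndarray | int) -> np.ndarray | int:
    """Calendar month (1..12) of a flat monthly index starting in January."""
    return np.asarray(t) % 12 + 1 if isinstance(t, np.ndarray) else t % 12 + 1
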