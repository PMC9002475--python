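"""Area-percentage and distribution statistics by categorical mask.

Pixels are treated as equal-area (synthetic grids are abstract), so area
percent is simply a pixel-count fraction.  Quantiles use linear
interpolation between order statistics.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

PERCENTILES = (5, 25, 75, 95)


def area_percentage(category_raster: np.ndarray, mask: np.ndarray | None = None) -> pd.Series:
    """Percent of valid pixels in each class: 100 * count / valid total.

    ``mask`` (optional, bool) marks valid pixels; NaN categories are
    always excluded.  Percentages over classes sum to 100.
    """
    cats = np.asarray(category_raster)
    valid = np.ones(cats.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if np.issubdtype(cats.dtype, np.floating):
        valid = valid & np.isfinite(cats)
    vals = cats[valid]
    if vals.size == 0:
        warnings.warn("no valid pixels; empty area summary", stacklevel=2)
        return pd.Series(dtype=float, name="area_percent")
    classes, counts = np.unique(vals, return_counts=True)
    return pd.Series(100.0 * counts / vals.size, index=classes, name="area_percent")


def group_stats(value_raster: np.ndarray, category_raster: np.ndarray) -> pd.DataFrame:
    """Per-class count, area percent, mean, median, SD and percentiles.

    Only finite values enter the statistics; a class with no finite values
    is still reported, with count 0.
    """
    vals = np.asarray(value_raster, dtype=float).reshape(-1)
    cats = np.asarray(category_raster).reshape(-1)
    if vals.shape != cats.shape:
        raise ValueError("value and category rasters must be aligned")
    finite = np.isfinite(vals)
    total = int(finite.sum())
    rows = []
    for cls in np.unique(cats):
        v = vals[(cats == cls) & finite]
        row = {"class": cls, "count": int(v.size),
               "area_percent": 100.0 * v.size / total if total else np.nan}
        if v.size:
            row.update(mean=v.mean(), median=np.median(v), sd=v.std(ddof=1) if v.size > 1 else 0.0)
            for p in PERCENTILES:
                row[f"p{p}"] = np.percentile(v, p)  # linear interpolation
        else:
            row.update(mean=np.nan, median=np.nan, sd=np.nan,
                       **{f"p{p}": np.nan for p in PERCENTILES})
        rows.append(row)
    return pd.DataFrame(rows).set_index("class")
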