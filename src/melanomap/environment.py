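"""Annual climate means per grid cell.

Monthly (or hourly-within-month) raster stacks of insolation (INS, W m^-2),
air temperature (TMP, deg C) and relative humidity (HUM, %) are collapsed to
annual per-pixel means and then aggregated to grid cells by area-weighted
averaging of the pixels each cell covers.  Months are weighted equally;
hours within a month are averaged before months are pooled.  Missing pixels
propagate: a cell with no data is flagged missing, never silently zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import EqualAreaGrid
from .raster import GeometryError, Raster

VARIABLES = ("INS", "TMP", "HUM")


def annual_mean(layer_stack: list[Raster]) -> Raster:
    """Per-pixel unweighted mean across layers; NaN propagates."""
    if not layer_stack:
        raise ValueError("need at least one layer")
    first = layer_stack[0]
    for layer in layer_stack[1:]:
        if not layer.same_geometry(first):
            raise GeometryError("layers differ in shape, georeferencing or CRS")
    return first.with_data(np.mean([r.data for r in layer_stack], axis=0))


def aggregate_to_grid(raster: Raster, grid: EqualAreaGrid) -> np.ndarray:
    """Area-weighted mean of raster pixels per grid cell.

    Pixels and cells are axis-aligned squares in the same projected CRS, so
    the overlap weight of pixel and cell is the product of their interval
    overlaps in x and y.  Cells with zero data coverage get NaN; if no cell
    overlaps the raster at all, that is an error.
    """
    if raster.crs != grid.crs:
        raise GeometryError(
            f"raster CRS {raster.crs!r} != grid CRS {grid.crs!r}; "
            "reprojection is not supported — supply data in the grid CRS")
    ny, nx = raster.shape
    res = raster.res
    px_left = raster.x0 + np.arange(nx) * res
    # row 0 is the northern row
    px_bottom = raster.y_top - (np.arange(ny) + 1) * res

    s = grid.cell_size
    gx0, gy0 = grid.origin
    out = np.full(grid.n_cells, np.nan)
    data = raster.data
    for k, (r, c) in enumerate(zip(grid.rows, grid.cols)):
        cx0, cy0 = gx0 + c * s, gy0 + r * s
        wx = np.clip(np.minimum(px_left + res, cx0 + s)
                     - np.maximum(px_left, cx0), 0.0, None)
        wy = np.clip(np.minimum(px_bottom + res, cy0 + s)
                     - np.maximum(px_bottom, cy0), 0.0, None)
        w = np.outer(wy, wx)
        valid = np.isfinite(data) & (w > 0)
        wsum = w[valid].sum()
        if wsum > 0:
            out[k] = float((w[valid] * data[valid]).sum() / wsum)
    if np.all(np.isnan(out)):
        raise GeometryError("raster and grid do not overlap")
    return out


def build_cell_environment(monthly: dict[str, list[Raster]],
                           grid: EqualAreaGrid) -> pd.DataFrame:
    """Annual INS / TMP / HUM per cell from monthly stacks.

    Returns a DataFrame keyed by cell_id with one column per variable;
    cells without raster coverage carry NaN and should be treated as
    missing downstream.
    """
    cols = {"cell_id": grid.cell_ids}
    for var in VARIABLES:
        if var not in monthly:
            raise KeyError(f"missing variable {var}")
        cols[var] = aggregate_to_grid(annual_mean(monthly[var]), grid)
    df = pd.DataFrame(cols)
    hum = df["HUM"].dropna()
    if ((hum < 0) | (hum > 100)).any():
        raise ValueError("relative humidity outside [0, 100]%")
    return df
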