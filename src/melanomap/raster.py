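"""Minimal georeferenced raster container.

All data in this project live in a single projected equal-area plane
(metres), so a raster is fully described by a 2-D array, the coordinate of
its top-left corner, a square pixel size, and a CRS label.  Rasters are
written as plain single- or multi-page TIFF with a JSON sidecar carrying the
georeferencing (``<name>.tif`` + ``<name>.tif.json``).  Operations never
reproject: combining rasters with different CRS labels is an error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


class GeometryError(ValueError):
    """Raster geometries (shape, origin, resolution, CRS) do not match."""


@dataclass(frozen=True)
class Raster:
    """A single-band raster on a projected plane.

    Row 0 is the northernmost row; pixel (i, j) covers the half-open square
    ``[x0 + j*res, x0 + (j+1)*res) x (y_top - (i+1)*res, y_top - i*res]``.
    Missing data are NaN.
    """

    data: np.ndarray          # (ny, nx) float64
    x0: float                 # west edge, metres
    y_top: float              # north edge, metres
    res: float                # pixel size, metres
    crs: str                  # e.g. "EPSG:102008" or a synthetic label

    def __post_init__(self) -> None:
        if self.res <= 0:
            raise ValueError(f"pixel resolution must be positive, got {self.res}")
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        object.__setattr__(self, "data", np.asarray(self.data, dtype=np.float64))

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) of the covered rectangle."""
        ny, nx = self.data.shape
        return (self.x0, self.y_top - ny * self.res,
                self.x0 + nx * self.res, self.y_top)

    def x_centers(self) -> np.ndarray:
        nx = self.data.shape[1]
        return self.x0 + (np.arange(nx) + 0.5) * self.res

    def y_centers(self) -> np.ndarray:
        """North-to-south, matching row order."""
        ny = self.data.shape[0]
        return self.y_top - (np.arange(ny) + 0.5) * self.res

    def same_geometry(self, other: "Raster") -> bool:
        return (self.data.shape == other.data.shape
                and self.x0 == other.x0 and self.y_top == other.y_top
                and self.res == other.res and self.crs == other.crs)

    def with_data(self, data: np.ndarray) -> "Raster":
        return Raster(np.asarray(data, dtype=np.float64),
                      self.x0, self.y_top, self.res, self.crs)


def write_raster(path: str | Path, layers: Raster | list[Raster]) -> None:
    """Write one raster (single page) or a stack (one page per layer)."""
    path = Path(path)
    stack = [layers] if isinstance(layers, Raster) else list(layers)
    first = stack[0]
    for layer in stack[1:]:
        if not layer.same_geometry(first):
            raise GeometryError("all layers in a stack must share geometry")
    tifffile.imwrite(path, np.stack([r.data.astype(np.float32) for r in stack]))
    sidecar = {"x0": first.x0, "y_top": first.y_top, "res": first.res,
               "crs": first.crs, "n_layers": len(stack)}
    Path(f"{path}.json").write_text(json.dumps(sidecar, indent=1))


def read_raster(path: str | Path) -> list[Raster]:
    """Read a TIFF written by :func:`write_raster`; always returns a list."""
    path = Path(path)
    meta = json.loads(Path(f"{path}.json").read_text())
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    return [Raster(arr[i].astype(np.float64), meta["x0"], meta["y_top"],
                   meta["res"], meta["crs"]) for i in range(arr.shape[0])]
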