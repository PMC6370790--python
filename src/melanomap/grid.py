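"""Equal-area grids, presence matrices, and assemblage mean lightness.

Species range polygons are converted to a boolean cells x species presence
matrix on a square equal-area grid (50 km cells by default, mirroring the
Albers-projection grids used for continental butterfly atlases).  The
assemblage trait of a cell is the unweighted mean lightness of the species
present, subject to a minimum-richness filter that stabilizes the estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry


@dataclass(frozen=True)
class EqualAreaGrid:
    """Square cells on a projected equal-area plane.

    Cell (row, col) covers the half-open square
    ``[x0 + col*s, x0 + (col+1)*s) x [y0 + row*s, y0 + (row+1)*s)`` with
    ``s = cell_size``; the origin is snapped down to a multiple of the cell
    size so the grid is reproducible without a reference grid file.
    """

    crs: str
    cell_size: float
    origin: tuple[float, float]
    rows: np.ndarray              # (n_cells,) int
    cols: np.ndarray              # (n_cells,) int

    @property
    def n_cells(self) -> int:
        return len(self.rows)

    @property
    def cell_ids(self) -> list[str]:
        return [f"r{r}c{c}" for r, c in zip(self.rows, self.cols)]

    def cell_polygon(self, row: int, col: int) -> BaseGeometry:
        s = self.cell_size
        x0, y0 = self.origin
        return shapely.box(x0 + col * s, y0 + row * s,
                           x0 + (col + 1) * s, y0 + (row + 1) * s)

    def cell_polygons(self) -> list[BaseGeometry]:
        return [self.cell_polygon(r, c) for r, c in zip(self.rows, self.cols)]

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) centre coordinates in metres."""
        s = self.cell_size
        x0, y0 = self.origin
        return np.column_stack([x0 + (self.cols + 0.5) * s,
                                y0 + (self.rows + 0.5) * s])

    def to_frame(self) -> pd.DataFrame:
        s = self.cell_size
        x0, y0 = self.origin
        return pd.DataFrame({
            "cell_id": self.cell_ids, "row": self.rows, "col": self.cols,
            "x_min": x0 + self.cols * s, "y_min": y0 + self.rows * s,
            "crs": self.crs, "cell_size": s})


def grid_from_frame(df: pd.DataFrame) -> EqualAreaGrid:
    """Rebuild a grid from its CSV interface (inverse of ``to_frame``)."""
    s = float(df["cell_size"].iloc[0])
    x0 = float((df["x_min"] - df["col"] * s).iloc[0])
    y0 = float((df["y_min"] - df["row"] * s).iloc[0])
    return EqualAreaGrid(crs=str(df["crs"].iloc[0]), cell_size=s,
                         origin=(x0, y0),
                         rows=df["row"].to_numpy(dtype=int),
                         cols=df["col"].to_numpy(dtype=int))


def make_grid(extent_polygon: BaseGeometry, cell_size: float = 50_000.0,
              crs: str = "EPSG:102008") -> EqualAreaGrid:
    """Lay a square grid over an extent, keeping cells that overlap it.

    Only cells whose intersection with the extent has positive area are
    retained (a cell merely touching the boundary is not part of the grid).
    """
    if cell_size <= 0:
        raise ValueError(f"cell_size must be positive, got {cell_size}")
    if extent_polygon.is_empty or extent_polygon.area <= 0:
        raise ValueError("extent polygon is empty or degenerate")
    minx, miny, maxx, maxy = extent_polygon.bounds
    x0 = np.floor(minx / cell_size) * cell_size
    y0 = np.floor(miny / cell_size) * cell_size
    ncols = int(np.ceil((maxx - x0) / cell_size))
    nrows = int(np.ceil((maxy - y0) / cell_size))
    rows, cols = [], []
    for r in range(nrows):
        for c in range(ncols):
            cell = shapely.box(x0 + c * cell_size, y0 + r * cell_size,
                               x0 + (c + 1) * cell_size, y0 + (r + 1) * cell_size)
            if extent_polygon.intersection(cell).area > 0:
                rows.append(r)
                cols.append(c)
    return EqualAreaGrid(crs=crs, cell_size=float(cell_size),
                         origin=(float(x0), float(y0)),
                         rows=np.array(rows, dtype=int),
                         cols=np.array(cols, dtype=int))


@dataclass(frozen=True)
class PresenceGrid:
    """Boolean cells x species matrix with its grid geometry."""

    grid: EqualAreaGrid
    species_ids: list[str]
    presence: np.ndarray          # (n_cells, n_species) bool

    @property
    def richness(self) -> np.ndarray:
        return self.presence.sum(axis=1)

    def occupied_cell_counts(self) -> np.ndarray:
        return self.presence.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.presence.astype(int),
                            index=pd.Index(self.grid.cell_ids, name="cell_id"),
                            columns=self.species_ids)

    def to_triplets(self) -> pd.DataFrame:
        cell_idx, sp_idx = np.nonzero(self.presence)
        ids = self.grid.cell_ids
        return pd.DataFrame({
            "cell_id": [ids[i] for i in cell_idx],
            "species_id": [self.species_ids[j] for j in sp_idx],
            "present": 1})


def merge_ranges_by_complex(ranges: dict[str, BaseGeometry | None],
                            complex_map: dict[str, str]
                            ) -> dict[str, BaseGeometry | None]:
    """Union member ranges into one range per species complex.

    The complex enters the presence matrix as a single column whose range is
    the union of its members' ranges; non-members pass through.
    """
    out: dict[str, BaseGeometry | None] = {}
    members: dict[str, list[BaseGeometry]] = {}
    for sid, geom in ranges.items():
        cid = complex_map.get(sid)
        if cid is None:
            out[sid] = geom
        elif geom is not None:
            members.setdefault(cid, []).append(geom)
        else:
            members.setdefault(cid, [])
    for cid, geoms in members.items():
        out[cid] = shapely.union_all(geoms) if geoms else None
    return out


def rasterize_ranges(range_polygons: dict[str, BaseGeometry | None],
                     grid: EqualAreaGrid) -> PresenceGrid:
    """Presence = positive-area overlap between a range and a cell.

    A polygon touching a cell only along its boundary does not make the
    species present there.  Invalid geometries are repaired with
    ``make_valid`` when possible; irreparable ones raise, naming the species.
    """
    species_ids = sorted(range_polygons)
    cells = grid.cell_polygons()
    tree = shapely.STRtree(cells)
    presence = np.zeros((grid.n_cells, len(species_ids)), dtype=bool)
    for j, sid in enumerate(species_ids):
        geom = range_polygons[sid]
        if geom is None:
            continue
        if not geom.is_valid:
            geom = shapely.make_valid(geom)
            if geom.is_empty or not geom.is_valid:
                raise ValueError(f"unrepairable range geometry for {sid}")
        for i in tree.query(geom):
            if geom.intersection(cells[i]).area > 0:
                presence[i, j] = True
    return PresenceGrid(grid=grid, species_ids=species_ids, presence=presence)


@dataclass(frozen=True)
class AssemblageResult:
    """Per-cell mean lightness for one (side, family scope) combination."""

    table: pd.DataFrame           # cell_id, side, family_scope, mean_lightness, n_species
    n_cells_excluded: int         # cells dropped by the richness filter


def assemblage_mean(presence: PresenceGrid, traits: dict,
                    side: str, family_scope: str = "all",
                    min_richness: int = 5) -> AssemblageResult:
    """Unweighted mean lightness of the species present in each cell.

    ``traits`` maps species_id -> SpeciesTrait.  With a family scope, both
    the species set and the richness filter are restricted to that family;
    cells with fewer than ``min_richness`` in-scope species are excluded
    (and counted), stabilizing the assemblage estimate.
    """
    if side not in ("dorsal", "ventral"):
        raise ValueError(f"side must be dorsal or ventral, got {side!r}")
    present_sids = [sid for sid, n in
                    zip(presence.species_ids, presence.occupied_cell_counts())
                    if n > 0]
    missing = [sid for sid in present_sids if sid not in traits]
    if missing:
        raise ValueError(f"species present but traitless: {missing}")

    in_scope = np.array([
        sid in traits
        and (family_scope == "all" or traits[sid].family == family_scope)
        for sid in presence.species_ids])
    sub = presence.presence[:, in_scope]
    values = np.array([traits[sid].lightness(side)
                       for sid, keep in zip(presence.species_ids, in_scope)
                       if keep])
    richness = sub.sum(axis=1)
    keep_cells = richness >= min_richness
    with np.errstate(invalid="ignore"):
        sums = sub @ values if values.size else np.zeros(len(richness))
        means = np.divide(sums, richness, out=np.full(len(richness), np.nan),
                          where=richness > 0)
    ids = presence.grid.cell_ids
    table = pd.DataFrame({
        "cell_id": [ids[i] for i in np.flatnonzero(keep_cells)],
        "side": side, "family_scope": family_scope,
        "mean_lightness": means[keep_cells],
        "n_species": richness[keep_cells].astype(int)})
    return AssemblageResult(table=table,
                            n_cells_excluded=int((~keep_cells).sum()))


def quantile_bins(values: np.ndarray, k: int) -> np.ndarray:
    """Zero-based quantile bin index per value.

    Bin edges are the 1/k ... (k-1)/k sample quantiles; a value equal to an
    edge falls in the lower bin.  All-equal input collapses to a single bin
    with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values to bin")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if np.all(values == values[0]):
        warnings.warn("all values equal; single quantile bin", stacklevel=2)
        return np.zeros(values.shape, dtype=int)
    edges = np.quantile(values, np.arange(1, k) / k)
    return np.searchsorted(edges, values, side="left").astype(int)
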