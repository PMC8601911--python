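"""Conservation-area footprints and network-level evaluation.

A :class:`Footprint` is a set of 1-km² grid cells (row, col).  The network is
hierarchical: large Focal Landscapes each contain several disjoint Grassland
Bird Conservation Areas (GBCAs); a "GBCA ensemble" is the union of the GBCAs
of one Focal Landscape.

Evaluation operations compute, from a predicted density surface,

* the baseline mean density inside an area (with a 500-m boundary buffer so
  every cell touching the boundary is included),
* the percentage of the statewide population inside a set of areas, checked
  against the 20% planning target and the 10% IUCN threshold, and
* the optimal minimum set: the smallest number of cells whose summed
  population reaches a target fraction of the statewide total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import box
from shapely.ops import unary_union

from .errors import ConfigurationError, GrassnetError
from .geometry import GridGeometry


@dataclass(frozen=True)
class Footprint:
    """Set of coarse-grid cells forming one conservation area."""

    name: str
    cells: np.ndarray  # (k, 2) int array of (row, col)

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=int)
        if cells.ndim != 2 or cells.shape[1] != 2 or cells.shape[0] == 0:
            raise ConfigurationError("footprint cells must be a nonempty (k, 2) array")
        object.__setattr__(self, "cells", cells)

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]

    def area_km2(self, geometry: GridGeometry) -> float:
        return self.n_cells * (geometry.cellsize / 1000.0) ** 2

    def cell_set(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in self.cells}

    def within(self, geometry: GridGeometry) -> bool:
        r, c = self.cells[:, 0], self.cells[:, 1]
        return bool(
            (r >= 0).all() & (r < geometry.nrows).all() & (c >= 0).all() & (c < geometry.ncols).all()
        )

    def polygon(self, geometry: GridGeometry) -> shapely.Geometry:
        """Union of the cell squares in map coordinates."""
        s = geometry.cellsize
        boxes = [
            box(
                geometry.x0 + c * s,
                geometry.y0 - (r + 1) * s,
                geometry.x0 + (c + 1) * s,
                geometry.y0 - r * s,
            )
            for r, c in self.cells
        ]
        return unary_union(boxes)

    def mask(self, geometry: GridGeometry) -> np.ndarray:
        m = np.zeros(geometry.shape, dtype=bool)
        m[self.cells[:, 0], self.cells[:, 1]] = True
        return m


@dataclass(frozen=True)
class FocalLandscape:
    """A Focal Landscape with its nested, pairwise-disjoint GBCAs."""

    footprint: Footprint
    gbcas: tuple[Footprint, ...] = ()

    @property
    def name(self) -> str:
        return self.footprint.name

    def gbca_ensemble(self) -> Footprint:
        """Union of all GBCAs of this landscape, as one footprint."""
        if not self.gbcas:
            raise GrassnetError(f"landscape {self.name!r} has no GBCAs")
        cells = np.vstack([g.cells for g in self.gbcas])
        return Footprint(name=f"{self.name}/ensemble", cells=cells)


@dataclass(frozen=True)
class ConservationNetwork:
    landscapes: tuple[FocalLandscape, ...]

    def __post_init__(self) -> None:
        for fl in self.landscapes:
            parent = fl.footprint.cell_set()
            seen: set[tuple[int, int]] = set()
            for g in fl.gbcas:
                cs = g.cell_set()
                if not cs <= parent:
                    raise ConfigurationError(
                        f"GBCA {g.name!r} is not nested in landscape {fl.name!r}"
                    )
                if cs & seen:
                    raise ConfigurationError(
                        f"GBCA {g.name!r} overlaps a sibling in landscape {fl.name!r}"
                    )
                seen |= cs

    def focal_footprints(self) -> list[Footprint]:
        return [fl.footprint for fl in self.landscapes]

    @property
    def total_cells(self) -> int:
        return sum(fl.footprint.n_cells for fl in self.landscapes)


@dataclass(frozen=True)
class MinimumSetResult:
    """Smallest cell set reaching a population target fraction."""

    cells: np.ndarray  # (k, 2) selected (row, col), in selection order
    achieved_fraction: float
    size_km2: float
    target_fraction: float


def footprint_cell_values(surface_layer: np.ndarray, footprint: Footprint) -> np.ndarray:
    return surface_layer[footprint.cells[:, 0], footprint.cells[:, 1]]


def buffered_cells(
    footprint: Footprint, geometry: GridGeometry, buffer_m: float
) -> np.ndarray:
    """Cells whose centers lie within ``buffer_m`` of the footprint polygon.

    With ``buffer_m = 0`` this returns exactly the footprint's own cells.
    The distance test is inclusive, so with 1-km cells a 500-m buffer picks
    up the ring of edge-adjacent cells (centers exactly 500 m from the
    boundary) but not the diagonal corners (√2·500 m away).
    """
    if buffer_m < 0:
        raise ConfigurationError("buffer_m must be >= 0")
    if buffer_m == 0:
        return footprint.cells.copy()
    poly = footprint.polygon(geometry)
    r0 = max(int(footprint.cells[:, 0].min() - np.ceil(buffer_m / geometry.cellsize)) - 1, 0)
    r1 = min(int(footprint.cells[:, 0].max() + np.ceil(buffer_m / geometry.cellsize)) + 2, geometry.nrows)
    c0 = max(int(footprint.cells[:, 1].min() - np.ceil(buffer_m / geometry.cellsize)) - 1, 0)
    c1 = min(int(footprint.cells[:, 1].max() + np.ceil(buffer_m / geometry.cellsize)) + 2, geometry.ncols)
    rows, cols = np.mgrid[r0:r1, c0:c1]
    rows, cols = rows.ravel(), cols.ravel()
    x, y = geometry.center_of(rows, cols)
    keep = shapely.dwithin(poly, shapely.points(x, y), buffer_m)
    cells = np.column_stack([rows[keep], cols[keep]])
    if cells.shape[0] == 0:
        raise GrassnetError(f"buffering left footprint {footprint.name!r} empty")
    return cells


def baseline_density(
    surface, footprint: Footprint, buffer_m: float = 500.0, layer: str = "point"
) -> tuple[float, int]:
    """Mean density (per km²) over the buffered footprint cells.

    Returns ``(mean_density, n_cells_included)``.
    """
    grid = surface.geometry
    if not footprint.within(grid):
        raise ConfigurationError(f"footprint {footprint.name!r} exceeds the grid")
    cells = buffered_cells(footprint, grid, buffer_m)
    vals = surface.layer(layer)[cells[:, 0], cells[:, 1]]
    return float(vals.mean()), int(cells.shape[0])


def percent_statewide(
    surface, footprints: list[Footprint], layer: str = "point"
) -> float:
    """Percent of the statewide population inside the union of footprints.

    Population in a cell is density × cell area; overlapping footprint cells
    are counted once.  Compared downstream against the 20% conservation
    target and the 10% IUCN critically-endangered threshold.
    """
    vals = surface.layer(layer)
    total = float(vals.sum())
    if total <= 0:
        raise GrassnetError("statewide population is zero; percentage undefined")
    mask = np.zeros(surface.geometry.shape, dtype=bool)
    for fp in footprints:
        mask[fp.cells[:, 0], fp.cells[:, 1]] = True
    return 100.0 * float(vals[mask].sum()) / total


def minimum_set(
    surface, target_frac: float = 0.20, layer: str = "point"
) -> MinimumSetResult:
    """Smallest set of cells whose summed population reaches the target.

    Cells are taken in descending density order (ties broken by row-major
    cell order), which is provably minimal for this objective.  A relative
    tolerance of 1e-12 on the cumulative-sum comparison guards against float
    round-off on exact-fraction cases (e.g. a uniform surface).
    """
    if not 0 < target_frac <= 1:
        raise ConfigurationError("target_frac must lie in (0, 1]")
    vals = surface.layer(layer)
    total = float(vals.sum())
    if total <= 0:
        raise GrassnetError("all-zero surface; minimum set undefined")
    flat = vals.ravel()
    nrows, ncols = vals.shape
    rows, cols = np.divmod(np.arange(flat.size), ncols)
    # descending value, ascending (row, col) among ties
    order = np.lexsort((cols, rows, -flat))
    csum = np.cumsum(flat[order])
    target = target_frac * total
    k = int(np.searchsorted(csum, target * (1 - 1e-12)) + 1)
    k = min(k, flat.size)
    sel = order[:k]
    cell_area = (surface.geometry.cellsize / 1000.0) ** 2
    return MinimumSetResult(
        cells=np.column_stack([rows[sel], cols[sel]]),
        achieved_fraction=float(csum[k - 1] / total),
        size_km2=k * cell_area,
        target_fraction=target_frac,
    )
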