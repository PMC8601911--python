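"""Planar grid geometry shared by all rasters and surfaces.

Grids are row-major with the origin at the upper-left corner; cell intervals
are half-open, so a point on the right/bottom edge of a cell belongs to the
next cell.  Coordinates are projected planar meters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a regular grid.

    Parameters
    ----------
    nrows, ncols
        Grid shape.
    cellsize
        Cell edge length in meters.
    x0, y0
        Coordinates of the upper-left corner of cell (0, 0).
    """

    nrows: int
    ncols: int
    cellsize: float
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if self.nrows <= 0 or self.ncols <= 0:
            raise ValueError("grid shape must be positive")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def width(self) -> float:
        return self.ncols * self.cellsize

    @property
    def height(self) -> float:
        return self.nrows * self.cellsize

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates as (X, Y) arrays of shape (nrows, ncols)."""
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = self.y0 - (np.arange(self.nrows) + 0.5) * self.cellsize
        return np.meshgrid(xs, ys)

    def center_of(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.x0 + (col + 0.5) * self.cellsize
        y = self.y0 - (row + 0.5) * self.cellsize
        return x, y

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cell (row, col) containing each point; half-open intervals."""
        col = np.floor((np.asarray(x) - self.x0) / self.cellsize).astype(int)
        row = np.floor((self.y0 - np.asarray(y)) / self.cellsize).astype(int)
        return row, col

    def contains_point(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        y = np.asarray(y)
        return (
            (x >= self.x0)
            & (x < self.x0 + self.width)
            & (y <= self.y0)
            & (y > self.y0 - self.height)
        )

    def coarsen(self, coarse_cellsize: float) -> "GridGeometry":
        """Aligned coarse geometry; the factor must be an exact integer divisor."""
        factor = coarse_cellsize / self.cellsize
        if abs(factor - round(factor)) > 1e-9:
            raise ValueError("coarse cellsize must be an integer multiple of fine")
        factor = int(round(factor))
        if self.nrows % factor or self.ncols % factor:
            raise ValueError("fine grid shape must be divisible by the coarsening factor")
        return GridGeometry(
            self.nrows // factor, self.ncols // factor, coarse_cellsize, self.x0, self.y0
        )
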