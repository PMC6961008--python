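"""Georeferenced raster grids.

A :class:`RasterGrid` is the carrier for every 2-D product in the toolkit:
digital surface models, canopy height models, per-channel LiDAR intensity
images, NDVI, and integer crown label maps.  The grid lives on a regular
square-cell lattice anchored at its upper-left corner in world (map)
coordinates, with rows increasing southwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RasterGrid", "world_to_cell"]


def world_to_cell(
    x: np.ndarray | float,
    y: np.ndarray | float,
    origin: tuple[float, float],
    cell_size: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Map world coordinates to (row, col) indices.

    Cells are half-open: a cell (i, j) covers
    ``[x0 + j*cs, x0 + (j+1)*cs)`` in x and ``(y0 - (i+1)*cs, y0 - i*cs]``
    in y, so a point exactly on a shared edge belongs to exactly one cell
    (the top edge of a row and the left edge of a column are inclusive).
    """
    x0, y0 = origin
    col = np.floor((np.asarray(x, dtype=float) - x0) / cell_size).astype(np.int64)
    row = np.floor((y0 - np.asarray(y, dtype=float)) / cell_size).astype(np.int64)
    # top row boundary: y == y0 gives t == 0 -> row 0 (inclusive edge)
    return row, col


@dataclass
class RasterGrid:
    """A 2-D grid of values with square cells and a nodata mask.

    Parameters
    ----------
    values : ndarray of shape (nrows, ncols)
        Cell values; entries under ``nodata_mask`` are ignored.
    cell_size : float
        Side length of a cell in metres (> 0).
    origin : (float, float)
        World coordinates (x, y) of the grid's upper-left corner.
    nodata_mask : ndarray of bool, same shape
        True where the cell holds no data.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("values and nodata_mask shapes differ")
        self.origin = (float(self.origin[0]), float(self.origin[1]))
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise ValueError("non-finite value at a valid (non-nodata) cell")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_geometry(self, other: "RasterGrid", *, tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )

    def require_same_geometry(self, other: "RasterGrid", what: str = "raster") -> None:
        if not self.same_geometry(other):
            raise ValueError(f"{what}: grid geometries do not match")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """World coordinates (x, y) of all cell centres, each shaped like the grid."""
        nr, nc = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(nc) + 0.5) * self.cell_size
        ys = y0 - (np.arange(nr) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def world_to_cell(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        return world_to_cell(x, y, self.origin, self.cell_size)

    # -- convenience --------------------------------------------------------
    @property
    def valid(self) -> np.ndarray:
        return ~self.nodata_mask

    def copy_with(self, values: np.ndarray, nodata_mask: np.ndarray | None = None) -> "RasterGrid":
        if nodata_mask is None:
            nodata_mask = self.nodata_mask.copy()
        return RasterGrid(np.asarray(values, dtype=float), self.cell_size, self.origin, nodata_mask)

    def filled(self, fill_value: float = np.nan) -> np.ndarray:
        out = self.values.copy()
        out[self.nodata_mask] = fill_value
        return out
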