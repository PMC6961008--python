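"""Rasterization and preprocessing of multispectral LiDAR data.

Implements the standard chain from point records to analysis-ready rasters:
first-return maximum rasterization of DSM and intensity, inverse-distance
filling of empty cells, CHM = DSM - DEM, 3x3 Gaussian smoothing, NDVI from
the 1064/532 nm channels, and the vegetation mask that removes low-NDVI,
low-height pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster import RasterGrid
from .scene import PointCloud

__all__ = [
    "GridDefinition",
    "rasterize_first_returns",
    "idw_fill",
    "compute_chm",
    "gaussian_smooth_3x3",
    "compute_ndvi",
    "build_tree_mask",
]

log = logging.getLogger(__name__)

#: Vegetation-index threshold separating vegetated from non-vegetated pixels.
DEFAULT_NDVI_THRESH = 0.25
#: Height (m) below which a pixel is not considered part of a tree crown.
DEFAULT_HEIGHT_THRESH = 4.0


@dataclass(frozen=True)
class GridDefinition:
    """Target lattice for rasterization: cell size plus world extent.

    ``origin`` is the upper-left corner; the grid spans ``nrows`` x ``ncols``
    cells southwards/eastwards from it.
    """

    cell_size: float
    origin: tuple[float, float]
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one cell")

    @classmethod
    def from_extent(
        cls, x_min: float, y_min: float, x_max: float, y_max: float, cell_size: float
    ) -> "GridDefinition":
        ncols = max(1, int(np.ceil((x_max - x_min) / cell_size)))
        nrows = max(1, int(np.ceil((y_max - y_min) / cell_size)))
        return cls(cell_size, (x_min, y_max), nrows, ncols)


def rasterize_first_returns(
    points: PointCloud, grid_def: GridDefinition, channel: int
) -> tuple[RasterGrid, RasterGrid]:
    """Rasterize first returns of one channel into DSM and intensity grids.

    Each cell holding at least one first-return point receives the maximum
    z among those points, and the intensity of that same point.  Cells with
    no first return are flagged nodata.  Points outside the grid extent are
    dropped (with a logged count).
    """
    if not isinstance(points, PointCloud):
        points = PointCloud.from_points(points)
    if len(points) == 0:
        raise ValueError("cannot rasterize an empty point set")

    pts = points.select((points.channel == channel) & (points.return_number == 1))
    nr, nc = grid_def.nrows, grid_def.ncols
    dsm = np.full((nr, nc), np.nan)
    inten = np.full((nr, nc), np.nan)

    if len(pts):
        row, col = RasterGrid(
            np.zeros((nr, nc)), grid_def.cell_size, grid_def.origin
        ).world_to_cell(pts.x, pts.y)
        inside = (row >= 0) & (row < nr) & (col >= 0) & (col < nc)
        n_out = int(np.sum(~inside))
        if n_out:
            log.info("rasterize_first_returns: dropped %d points outside extent", n_out)
        row, col, z, ii = row[inside], col[inside], pts.z[inside], pts.intensity[inside]
        # stable per-cell argmax of z: sort by (flat cell, z) and keep the last
        flat = row * nc + col
        order = np.lexsort((z, flat))
        flat, z, ii = flat[order], z[order], ii[order]
        last = np.r_[flat[1:] != flat[:-1], True]
        dsm.ravel()[flat[last]] = z[last]
        inten.ravel()[flat[last]] = ii[last]

    nodata = np.isnan(dsm)
    dsm_grid = RasterGrid(np.where(nodata, 0.0, dsm), grid_def.cell_size, grid_def.origin, nodata)
    int_grid = RasterGrid(np.where(nodata, 0.0, inten), grid_def.cell_size, grid_def.origin, nodata.copy())
    return dsm_grid, int_grid


def idw_fill(grid: RasterGrid, power: float = 2.0, search_radius: int = 3) -> RasterGrid:
    """Fill nodata cells by inverse-distance-weighted interpolation.

    Every nodata cell with at least one valid cell within ``search_radius``
    cells (Euclidean, in cell units) receives the weighted mean of those
    cells with weights ``1/d**power``.  Valid cells pass through unchanged;
    unreachable cells stay nodata.
    """
    if grid.valid.sum() == 0:
        raise ValueError("cannot interpolate an all-nodata grid")
    if not grid.nodata_mask.any():
        return grid.copy_with(grid.values.copy())

    values = np.where(grid.valid, grid.values, 0.0)
    valid = grid.valid.astype(float)
    num = np.zeros(grid.shape)
    den = np.zeros(grid.shape)
    r = int(search_radius)
    for di in range(-r, r + 1):
        for dj in range(-r, r + 1):
            d = np.hypot(di, dj)
            if d == 0 or d > search_radius:
                continue
            w = d ** (-power)
            shifted_v = _shift(values, di, dj)
            shifted_m = _shift(valid, di, dj)
            num += w * shifted_v * shifted_m
            den += w * shifted_m
    fill = grid.nodata_mask & (den > 0)
    out = grid.values.copy()
    out[fill] = num[fill] / den[fill]
    out_nodata = grid.nodata_mask & ~fill
    out[out_nodata] = 0.0
    return RasterGrid(out, grid.cell_size, grid.origin, out_nodata)


def _shift(a: np.ndarray, di: int, dj: int) -> np.ndarray:
    """Shift ``a`` by (di, dj), zero-filling exposed cells."""
    out = np.zeros_like(a)
    nr, nc = a.shape
    src_i = slice(max(0, -di), min(nr, nr - di))
    dst_i = slice(max(0, di), min(nr, nr + di))
    src_j = slice(max(0, -dj), min(nc, nc - dj))
    dst_j = slice(max(0, dj), min(nc, nc + dj))
    out[dst_i, dst_j] = a[src_i, src_j]
    return out


def compute_chm(dsm: RasterGrid, dem: RasterGrid) -> RasterGrid:
    """Canopy height model: DSM minus DEM, clamped at zero from below.

    Small negative differences are registration artefacts and are clamped.
    Nodata in either input propagates.
    """
    dsm.require_same_geometry(dem, "compute_chm")
    nodata = dsm.nodata_mask | dem.nodata_mask
    chm = np.where(nodata, 0.0, np.maximum(dsm.values - dem.values, 0.0))
    return RasterGrid(chm, dsm.cell_size, dsm.origin, nodata)


def gaussian_smooth_3x3(grid: RasterGrid, sigma: float = 0.8) -> RasterGrid:
    """Smooth with a normalized 3x3 Gaussian kernel.

    Nodata cells are excluded and the kernel is renormalized over the
    contributing cells, so edges and nodata boundaries do not bleed.
    """
    k1 = np.exp(-0.5 * (np.arange(-1, 2) / sigma) ** 2)
    kernel = np.outer(k1, k1)
    kernel /= kernel.sum()
    vals = np.where(grid.valid, grid.values, 0.0)
    w = grid.valid.astype(float)
    num = ndimage.correlate(vals * w, kernel, mode="constant", cval=0.0)
    den = ndimage.correlate(w, kernel, mode="constant", cval=0.0)
    out = np.zeros_like(vals)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    nodata = grid.nodata_mask.copy()
    out[nodata] = 0.0
    return RasterGrid(out, grid.cell_size, grid.origin, nodata)


def compute_ndvi(i_nir: RasterGrid, i_green: RasterGrid) -> RasterGrid:
    """NDVI = (NIR - green) / (NIR + green) per cell.

    The NIR band is the 1064 nm channel and the green band the 532 nm
    channel.  Cells where both intensities are zero yield 0 by convention.
    """
    i_nir.require_same_geometry(i_green, "compute_ndvi")
    nir, green = i_nir.values, i_green.values
    if np.any(nir[i_nir.valid] < 0) or np.any(green[i_green.valid] < 0):
        raise ValueError("intensities must be non-negative")
    total = nir + green
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(total > 0, (nir - green) / np.where(total > 0, total, 1.0), 0.0)
    nodata = i_nir.nodata_mask | i_green.nodata_mask
    ndvi = np.where(nodata, 0.0, np.clip(ndvi, -1.0, 1.0))
    return RasterGrid(ndvi, i_nir.cell_size, i_nir.origin, nodata)


def build_tree_mask(
    chm: RasterGrid,
    ndvi: RasterGrid,
    ndvi_thresh: float = DEFAULT_NDVI_THRESH,
    height_thresh: float = DEFAULT_HEIGHT_THRESH,
    mode: str = "conjunctive",
) -> np.ndarray:
    """Boolean mask of tree pixels from NDVI and CHM thresholds.

    ``mode='conjunctive'`` (default): a pixel is a tree pixel iff
    NDVI >= ndvi_thresh AND CHM >= height_thresh — both vegetation evidence
    and height are required, so tall non-vegetated structures are excluded.

    ``mode='literal'``: a pixel is non-tree only when NDVI and CHM are
    *both* below their thresholds (the disjunctive-keep reading).
    """
    chm.require_same_geometry(ndvi, "build_tree_mask")
    low_ndvi = ndvi.values < ndvi_thresh
    low_chm = chm.values < height_thresh
    if mode == "conjunctive":
        mask = ~low_ndvi & ~low_chm
    elif mode == "literal":
        mask = ~(low_ndvi & low_chm)
    else:
        raise ValueError(f"unknown mask mode: {mode!r}")
    mask &= chm.valid & ndvi.valid
    return mask
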