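"""Marker-controlled watershed (MCW) baseline segmentation.

The comparison method: treetop regions act as markers, and a relief surface
built from the CHM and/or intensity gradients is flooded outward from the
markers with a deterministic priority queue.  Every masked-in pixel ends in
exactly one marker's basin.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .raster import RasterGrid
from .treetops import TreetopRegion

__all__ = ["FusedSurface", "fuse_surfaces", "mcw_segment"]


@dataclass
class FusedSurface:
    """Relief to flood, with a record of the sources that built it."""

    values: np.ndarray
    provenance: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def _gradient_magnitude(values: np.ndarray) -> np.ndarray:
    """Central-difference gradient magnitude with edge replication."""
    padded = np.pad(values, 1, mode="edge")
    gy = (padded[2:, 1:-1] - padded[:-2, 1:-1]) / 2.0
    gx = (padded[1:-1, 2:] - padded[1:-1, :-2]) / 2.0
    return np.hypot(gx, gy)


def _minmax(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    sel = values[mask]
    lo, hi = (sel.min(), sel.max()) if sel.size else (0.0, 0.0)
    if hi - lo <= 0:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def fuse_surfaces(
    sources: list[RasterGrid],
    mask: np.ndarray | None = None,
    relief: str = "gradient",
) -> FusedSurface:
    """Combine source rasters into a single non-negative relief.

    ``relief='gradient'``: per-source gradient magnitude, min-max normalized
    to [0, 1] over masked-in pixels, then averaged — boundaries between
    crowns become ridges regardless of the sources' units.
    ``relief='inverted-chm'``: the first source is treated as a CHM and
    inverted (max - CHM, normalized), so flooding climbs down the canopy.
    """
    if not sources:
        raise ValueError("fuse_surfaces needs at least one source")
    if mask is None:
        mask = np.ones(sources[0].shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if relief == "inverted-chm":
        chm = sources[0]
        vals = _minmax(chm.values.max() - chm.values, mask)
        return FusedSurface(vals, ["inverted-chm"])
    if relief != "gradient":
        raise ValueError(f"unknown relief mode: {relief!r}")
    acc = np.zeros(sources[0].shape)
    for src in sources:
        sources[0].require_same_geometry(src, "fuse_surfaces")
        acc += _minmax(_gradient_magnitude(src.values), mask)
    return FusedSurface(acc / len(sources), [f"gradient x{len(sources)}"])


def mcw_segment(
    surface: FusedSurface,
    markers: list[TreetopRegion],
    tree_mask: np.ndarray,
) -> np.ndarray:
    """Priority-flood watershed from marker regions, restricted to the mask.

    Flooding pops the pixel of lowest relief first; ties break on insertion
    order and then row-major position, making the labelling fully
    deterministic.  4-connectivity.  Returns an integer label map in which
    every masked-in pixel reachable from a marker carries that marker's id.
    """
    if not markers:
        raise ValueError("mcw_segment needs at least one marker")
    relief = surface.values
    nrows, ncols = relief.shape
    mask = np.asarray(tree_mask, dtype=bool)
    labels = np.zeros((nrows, ncols), dtype=np.int64)

    heap: list[tuple[float, int, int, int, int]] = []
    counter = 0
    for marker in markers:
        for r, c in zip(marker.rows.tolist(), marker.cols.tolist()):
            if not mask[r, c]:
                continue
            if labels[r, c] != 0 and labels[r, c] != marker.id:
                raise ValueError("markers overlap")
            labels[r, c] = marker.id
    for marker in markers:
        for r, c in zip(marker.rows.tolist(), marker.cols.tolist()):
            if mask[r, c]:
                heapq.heappush(heap, (float(relief[r, c]), counter, r, c, marker.id))
                counter += 1

    while heap:
        _, _, r, c, lab = heapq.heappop(heap)
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols and mask[rr, cc] and labels[rr, cc] == 0:
                labels[rr, cc] = lab
                heapq.heappush(heap, (float(relief[rr, cc]), counter, rr, cc, lab))
                counter += 1
    return labels
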