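"""Multi-scale morphological analysis of the CHM.

Grayscale opening with disk structuring elements (SEs) of increasing odd
pixel diameter removes bright canopy structure narrower than the SE.  The
mean of the opened CHM therefore decreases with SE diameter, and the most
negative steps of the differenced means mark diameters at which many crowns
are exactly swallowed — the dominant crown scales of the scene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .raster import RasterGrid

__all__ = [
    "ScaleCurve",
    "disk_structuring_element",
    "grayscale_open",
    "mean_difference_curve",
    "select_dominant_scales",
]


@dataclass(frozen=True)
class ScaleCurve:
    """Mean opened-CHM values over a diameter series and their differences.

    ``differences[j]`` = mean(open(d[j+1])) - mean(open(d[j])); the larger
    diameter is the minuend, and the difference is indexed by it.
    """

    diameters: np.ndarray
    means: np.ndarray
    differences: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.diameters) > 0):
            raise ValueError("diameters must be strictly increasing")
        if len(self.differences) != len(self.diameters) - 1:
            raise ValueError("need exactly one difference per adjacent diameter pair")

    @property
    def difference_diameters(self) -> np.ndarray:
        """Diameter labelling each difference (the minuend, i.e. larger one)."""
        return self.diameters[1:]


def disk_structuring_element(diameter: int) -> np.ndarray:
    """Boolean disk SE: cells within Euclidean distance (diameter-1)/2 of centre."""
    if diameter < 1 or diameter % 2 == 0:
        raise ValueError(f"SE diameter must be odd and positive, got {diameter}")
    r = (diameter - 1) // 2
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= r**2 + 1e-9


def grayscale_open(grid: RasterGrid, se: np.ndarray) -> RasterGrid:
    """Grayscale opening (erosion then dilation) with a flat SE.

    Cells outside the grid do not constrain the erosion (they act as +inf
    under the minimum) nor feed the dilation; nodata cells behave like cells
    outside the grid and stay nodata on output.
    """
    se = np.asarray(se, dtype=bool)
    if se.shape[0] > grid.shape[0] or se.shape[1] > grid.shape[1]:
        raise ValueError("structuring element larger than the grid")
    big = 1e30
    vals = np.where(grid.valid, grid.values, -big)
    eroded = ndimage.grey_erosion(vals, footprint=se, mode="constant", cval=big)
    opened = ndimage.grey_dilation(eroded, footprint=se, mode="constant", cval=-big)
    out = np.where(grid.valid, opened, 0.0)
    # a fully-invalid neighbourhood leaves -big behind; clamp to the data range
    out = np.where(out <= -big / 2, 0.0, out)
    return RasterGrid(out, grid.cell_size, grid.origin, grid.nodata_mask.copy())


def mean_difference_curve(
    chm: RasterGrid,
    mask: np.ndarray | None = None,
    d_start: int = 3,
    d_end: int = 73,
    step: int = 2,
) -> ScaleCurve:
    """Opened-CHM mean and adjacent-difference series over a diameter ladder.

    Means are taken over masked-in valid pixels only.  ``d_start`` must be
    odd and ``step`` even so every diameter in the ladder is odd.
    """
    if d_start % 2 == 0 or d_start < 1:
        raise ValueError("d_start must be odd and positive")
    if step % 2 != 0 or step < 2:
        raise ValueError("step must be a positive even number")
    if mask is None:
        mask = np.ones(chm.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool) & chm.valid
    if not mask.any():
        raise ValueError("mean_difference_curve: empty mask")

    diameters = np.arange(d_start, d_end + 1, step)
    means = np.empty(len(diameters))
    for i, d in enumerate(diameters):
        opened = grayscale_open(chm, disk_structuring_element(int(d)))
        means[i] = opened.values[mask].mean()
    return ScaleCurve(diameters=diameters, means=means, differences=np.diff(means))


def select_dominant_scales(
    curve: ScaleCurve,
    d_min: int = 5,
    d_max: int = 31,
    prominence: float = 0.05,
) -> list[int]:
    """Diameters at qualifying local minima of the difference curve, ascending.

    A local minimum must be strictly below both neighbours (a flat plateau
    counts once, at its smallest diameter) and its prominence must exceed
    ``prominence`` times the curve's total range — this suppresses the
    shallow minima produced by branch-scale texture and large tree clusters.
    The result is restricted to [d_min, d_max]; bounds encode prior knowledge
    of plausible crown sizes and are deliberately explicit configuration.
    """
    diffs = curve.differences
    dias = curve.difference_diameters
    if len(diffs) < 3:
        return []
    span = float(diffs.max() - diffs.min())
    if span <= 0:
        return []
    peaks, props = find_peaks(-diffs, prominence=prominence * span, plateau_size=(1, None))
    idx = props.get("left_edges", peaks)
    out = [int(dias[i]) for i in idx if d_min <= dias[i] <= d_max]
    return sorted(out)
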