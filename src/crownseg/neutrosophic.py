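"""Neutrosophic seeded region growing of tree crowns.

Crowns are grown outward from treetop seed regions.  Each candidate pixel is
judged in neutrosophic terms: the *indeterminacy* I (a saturating function
of the local variance over a 3x3 window) decides whether the pixel's own
value or its neighbourhood mean carries the evidence; the *truth* degree T
measures
per-channel similarity to the growing segment; truths are fused across
channels by an inverse-variance weighted mean S.  Homogeneous pixels
(I < 0.5) merge when S exceeds a fixed 0.6 cut; noisy pixels face a sigmoid
threshold that rises with I.  A crown-shape constraint on the CHM limits the
height step between the region contour and the candidate and forbids
climbing above the seed apex, preventing spill across crown boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster import RasterGrid
from .scene import MultiChannelScene
from .treetops import TreetopRegion

__all__ = [
    "NeutrosophicParams",
    "indeterminacy_degree",
    "truth_degree_pixel",
    "truth_degree_window",
    "combined_truth",
    "sigmoid_threshold",
    "window_statistics",
    "grow_crowns",
]

log = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-9


@dataclass(frozen=True)
class NeutrosophicParams:
    """Constants of the neutrosophic merging criterion.

    ``indeterminacy_cut`` switches between pixel-level and window-level
    truth; ``fixed_truth_cut`` is the merge threshold in the homogeneous
    regime; ``a1``/``a2``/``a3`` shape the sigmoid threshold used in the
    noisy regime; ``variance_scale`` normalizes window variance inside the
    indeterminacy measure.
    """

    indeterminacy_cut: float = 0.5
    fixed_truth_cut: float = 0.6
    a1: float = 1.0
    a2: float = 1.0
    a3: float = 4.5
    variance_scale: float = 100.0
    tau_h: float = 1.0
    literal_weighted_mean: bool = False
    shape_mode: str = "contour"

    def __post_init__(self) -> None:
        if not 0.0 < self.indeterminacy_cut < 1.0:
            raise ValueError("indeterminacy_cut must lie in (0, 1)")
        if self.a1 <= 0:
            raise ValueError("a1 must be positive")
        if self.shape_mode not in ("contour", "template"):
            raise ValueError(f"unknown shape_mode: {self.shape_mode!r}")


# -- primitives ------------------------------------------------------------


def indeterminacy_degree(
    variances: np.ndarray, variance_scale: float = 100.0
) -> float | np.ndarray:
    """I = mean over channels of (1 - exp(-sigma_i^2 / scale)); in [0, 1)."""
    v = np.asarray(variances, dtype=float)
    return np.mean(1.0 - np.exp(-v / variance_scale), axis=0)


def truth_degree_pixel(region_mean: float, pixel_value: float) -> float:
    """T = 1 - |mu(C) - rho| / rho, clamped to [0, 1].

    A zero pixel value yields T = 1 when the segment mean is also zero and
    T = 0 otherwise.
    """
    if pixel_value == 0:
        return 1.0 if region_mean == 0 else 0.0
    t = 1.0 - abs(region_mean - pixel_value) / pixel_value
    return min(max(t, 0.0), 1.0)


def truth_degree_window(region_mean: float, window_mean: float) -> float:
    """Window-level truth: as the pixel truth with the 3x3 mean in place of rho."""
    return truth_degree_pixel(region_mean, window_mean)


def combined_truth(
    truths: np.ndarray, variances: np.ndarray, literal: bool = False
) -> float:
    """Fuse per-channel truths into a final degree S.

    Default: inverse-variance weighted mean
    S = sum(T_i / sigma_i^2) / sum(1 / sigma_i^2) — noisier channels weigh
    less, equal variances give the plain mean, and S stays in [0, 1].
    ``literal=True`` evaluates sum(T_i * sigma_i^2) / sum(1 / sigma_i^2)
    instead (an unbounded form retained for comparison only).
    """
    t = np.asarray(truths, dtype=float)
    v = np.maximum(np.asarray(variances, dtype=float), VARIANCE_FLOOR)
    inv = 1.0 / v
    if literal:
        return float(np.sum(t * v) / np.sum(inv))
    return float(np.sum(t * inv) / np.sum(inv))


def sigmoid_threshold(I: float, params: NeutrosophicParams | None = None) -> float:
    """Indeterminacy-dependent merge threshold.

    F = (a1*I / (1 + exp(-a2*(I + a3))))^(1-I); with the defaults
    (1, 1, 4.5) this rises from ~0.70 at I = 0.5 to exactly 1 at I = 1.
    """
    p = params or NeutrosophicParams()
    base = p.a1 * I / (1.0 + np.exp(-p.a2 * (I + p.a3)))
    return float(base ** (1.0 - I))


def window_statistics(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel 3x3 window mean and (population) variance.

    Windows shrink at the image border: statistics are taken over the cells
    actually inside the grid.
    """
    ones = np.ones_like(values)
    kw = dict(size=3, mode="constant", cval=0.0)
    count = ndimage.uniform_filter(ones, **kw) * 9.0
    s1 = ndimage.uniform_filter(values, **kw) * 9.0
    s2 = ndimage.uniform_filter(values * values, **kw) * 9.0
    mean = s1 / count
    var = np.maximum(s2 / count - mean**2, 0.0)
    return mean, var


# -- region growing --------------------------------------------------------

_N4 = ((-1, 0), (1, 0), (0, -1), (0, 1))


class _Region:
    __slots__ = ("label", "count", "sums", "apex", "model")

    def __init__(self, label: int, n_channels: int, apex: float, model=None) -> None:
        self.label = label
        self.count = 0
        self.sums = [0.0] * n_channels
        self.apex = apex
        self.model = model

    def mean(self, c: int) -> float:
        return self.sums[c] / self.count


def grow_crowns(
    scene: MultiChannelScene,
    seeds: list[TreetopRegion],
    params: NeutrosophicParams | None = None,
    source: str = "both",
    fill: bool = True,
    fill_respects_shape: bool = False,
) -> np.ndarray:
    """Grow crown segments from treetop seeds; returns an integer label map.

    ``source`` selects the data feeding the neutrosophic criterion:
    ``'both'`` — the intensity channels, with the CHM enforcing the crown
    shape constraint; ``'intensity'`` — intensity channels only, shape
    constraint disabled; ``'chm'`` — the CHM as the sole channel (shape
    constraint kept).

    Growth proceeds in repeated raster-scan passes over the 4-adjacent
    frontier, merging immediately, until a pass changes nothing.  A pixel
    admissible to several regions joins the one with the highest fused truth
    (ties to the lowest label).  With ``fill=True`` the remaining masked-in
    pixels are then force-assigned to the adjacent region of maximal fused
    truth, so every reachable tree pixel ends inside some crown.
    """
    p = params or NeutrosophicParams()
    if source not in ("both", "intensity", "chm"):
        raise ValueError(f"unknown source mode: {source!r}")
    use_shape = source in ("both", "chm")

    chm = scene.chm.values
    mask = scene.tree_mask & scene.chm.valid
    nrows, ncols = chm.shape

    if source == "chm":
        stack = chm[None, :, :]
    else:
        stack = scene.intensity_stack()
    n_ch = stack.shape[0]

    win_mean = np.empty_like(stack)
    win_var = np.empty_like(stack)
    for c in range(n_ch):
        win_mean[c], win_var[c] = window_statistics(stack[c])
    indet = np.asarray(indeterminacy_degree(win_var, p.variance_scale))

    labels = np.zeros((nrows, ncols), dtype=np.int64)
    regions: dict[int, _Region] = {}
    for seed in seeds:
        lab = seed.id
        if np.any(labels[seed.rows, seed.cols] != 0):
            raise ValueError("seed regions overlap")
        reg = _Region(
            lab, n_ch, float(chm[seed.rows, seed.cols].max()), getattr(seed, "model", None)
        )
        for r, c in zip(seed.rows.tolist(), seed.cols.tolist()):
            labels[r, c] = lab
            reg.count += 1
            for ch in range(n_ch):
                reg.sums[ch] += float(stack[ch, r, c])
        regions[lab] = reg
    if not regions:
        return labels

    chm_l = chm.tolist()
    stack_l = [stack[c].tolist() for c in range(n_ch)]
    wmean_l = [win_mean[c].tolist() for c in range(n_ch)]
    wvar_l = [win_var[c].tolist() for c in range(n_ch)]
    indet_l = indet.tolist()
    mask_l = mask.tolist()

    def fused_truth(r: int, c: int, reg: _Region) -> tuple[float, float]:
        """(S, threshold) for merging pixel (r, c) into region ``reg``."""
        i_deg = indet_l[r][c]
        if i_deg < p.indeterminacy_cut:
            truths = [
                truth_degree_pixel(reg.mean(ch), stack_l[ch][r][c]) for ch in range(n_ch)
            ]
            thr = p.fixed_truth_cut
        else:
            truths = [
                truth_degree_window(reg.mean(ch), wmean_l[ch][r][c]) for ch in range(n_ch)
            ]
            thr = sigmoid_threshold(i_deg, p)
        variances = [wvar_l[ch][r][c] for ch in range(n_ch)]
        return combined_truth(truths, variances, p.literal_weighted_mean), thr

    cs = scene.chm.cell_size
    x0, y0 = scene.chm.origin

    def shape_ok(r: int, c: int, lab: int, reg: _Region) -> bool:
        """Crown-shape constraint against the adjacent contour pixel.

        In ``template`` mode the candidate height is instead compared to the
        seed's fitted Gaussian surface (contour rule for unfitted seeds).
        """
        cand = chm_l[r][c]
        if cand > reg.apex + 1e-9:
            return False
        if p.shape_mode == "template" and reg.model is not None:
            predicted = float(
                reg.model.evaluate(x0 + (c + 0.5) * cs, y0 - (r + 0.5) * cs)
            )
            return abs(cand - predicted) <= p.tau_h
        best = None
        for dr, dc in _N4:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols and labels[rr, cc] == lab:
                hval = chm_l[rr][cc]
                if best is None or hval > best:
                    best = hval
        if best is None:
            return False
        return abs(cand - best) <= p.tau_h

    def assign(r: int, c: int, reg: _Region) -> None:
        labels[r, c] = reg.label
        reg.count += 1
        for ch in range(n_ch):
            reg.sums[ch] += stack_l[ch][r][c]

    def neighbour_labels(r: int, c: int) -> list[int]:
        out = []
        for dr, dc in _N4:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols:
                lab = labels[rr, cc]
                if lab > 0 and lab not in out:
                    out.append(lab)
        return out

    # -- criterion phase: full frontier passes until stable ---------------
    changed = True
    n_merged = 0
    while changed:
        changed = False
        frontier = _frontier_pixels(labels, mask)
        for r, c in frontier:
            if labels[r, c] != 0:
                continue
            best_s, best_lab = -1.0, 0
            for lab in neighbour_labels(r, c):
                reg = regions[lab]
                s, thr = fused_truth(r, c, reg)
                if s <= thr:
                    continue
                if use_shape and not shape_ok(r, c, lab, reg):
                    continue
                if s > best_s or (s == best_s and lab < best_lab):
                    best_s, best_lab = s, lab
            if best_lab:
                assign(r, c, regions[best_lab])
                n_merged += 1
                changed = True

    # -- fill phase: force-assign remaining reachable tree pixels ---------
    n_filled = 0
    if fill:
        changed = True
        while changed:
            changed = False
            frontier = _frontier_pixels(labels, mask)
            for r, c in frontier:
                if labels[r, c] != 0:
                    continue
                best_s, best_lab = -1.0, 0
                for lab in neighbour_labels(r, c):
                    reg = regions[lab]
                    if fill_respects_shape and use_shape and not shape_ok(r, c, lab, reg):
                        continue
                    s, _thr = fused_truth(r, c, reg)
                    if s > best_s or (s == best_s and lab < best_lab):
                        best_s, best_lab = s, lab
                if best_lab:
                    assign(r, c, regions[best_lab])
                    n_filled += 1
                    changed = True

    log.info(
        "grow_crowns[%s]: %d seeds, %d pixels merged by criterion, %d filled",
        source,
        len(seeds),
        n_merged,
        n_filled,
    )
    return labels


def _frontier_pixels(labels: np.ndarray, mask: np.ndarray) -> list[tuple[int, int]]:
    """Unassigned masked-in pixels 4-adjacent to a labelled pixel, raster order."""
    lab = labels > 0
    grown = ndimage.binary_dilation(lab, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    cand = grown & ~lab & mask
    rows, cols = np.nonzero(cand)
    return list(zip(rows.tolist(), cols.tolist()))
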