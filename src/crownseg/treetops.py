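"""Multi-scale treetop detection with statistical cross-scale merging.

Treetops are detected as regional maxima of the morphologically opened CHM —
each detected region is the widest horizontal cross-section of a crown at
that scale.  Regions found at adjacent scales are reconciled bottom-up: an
upper-scale region that covers one or more lower-scale regions replaces them
only if neither of two one-sided F-tests flags it as a worse description of
a single crown.  The first test compares mean squared residuals of a
Gaussian crown surface fitted to each region; the second compares summed
per-channel intensity variances.  Either test significant at ``alpha`` means
the upper region likely straddles several crowns, and the lower regions win.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy import stats
from skimage.morphology import h_maxima, local_maxima

from .raster import RasterGrid
from .scales import disk_structuring_element, grayscale_open

__all__ = [
    "GaussianCrownModel",
    "TreetopRegion",
    "extract_treetop_regions",
    "fit_gaussian_crown",
    "residual_f_test",
    "intensity_f_test",
    "merge_across_scales",
    "disk_seeds_from_centres",
]

log = logging.getLogger(__name__)

#: Number of free parameters of the Gaussian crown surface.
N_PARAMS = 5
#: Residuals below this are treated as numerically perfect fits.
RESIDUAL_TOL = 1e-10
#: Floor applied to every variance estimate before forming ratios.
VARIANCE_FLOOR = 1e-9


@dataclass(frozen=True)
class GaussianCrownModel:
    """Fitted Gaussian crown surface A*exp(-(dx^2/2sx^2 + dy^2/2sy^2)).

    ``mu_x``/``mu_y`` locate the crown centre (the real treetop) in world
    coordinates; ``residual`` is the mean squared misfit over the region's
    ``n_pixels`` pixels.
    """

    A: float
    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float
    residual: float
    n_pixels: int

    def evaluate(self, x, y) -> np.ndarray:
        return self.A * np.exp(
            -(
                (np.asarray(x) - self.mu_x) ** 2 / (2 * self.sigma_x**2)
                + (np.asarray(y) - self.mu_y) ** 2 / (2 * self.sigma_y**2)
            )
        )


@dataclass(eq=False)
class TreetopRegion:
    """A detected crown cross-section at one scale."""

    id: int
    rows: np.ndarray
    cols: np.ndarray
    scale: int
    model: GaussianCrownModel | None = None
    intensity_variances: np.ndarray | None = None
    degenerate: bool = False
    _flat: frozenset = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def n_pixels(self) -> int:
        return len(self.rows)

    def flat_pixels(self, ncols: int) -> frozenset:
        if self._flat is None:
            object.__setattr__(self, "_flat", frozenset((self.rows * ncols + self.cols).tolist()))
        return self._flat

    def apex_height(self, chm: RasterGrid) -> float:
        return float(chm.values[self.rows, self.cols].max())

    def compute_intensity_variances(self, intensity_stack: np.ndarray) -> np.ndarray:
        """Per-channel sample variance (ddof=1, floored) over the region pixels."""
        vals = intensity_stack[:, self.rows, self.cols]
        if vals.shape[1] < 2:
            var = np.zeros(vals.shape[0])
        else:
            var = vals.var(axis=1, ddof=1)
        self.intensity_variances = np.maximum(var, VARIANCE_FLOOR)
        return self.intensity_variances


def extract_treetop_regions(
    opened: RasterGrid,
    tree_mask: np.ndarray,
    scale: int,
    start_id: int = 1,
    min_prominence: float = 0.0,
) -> list[TreetopRegion]:
    """Regional maxima of an opened CHM restricted to the tree mask.

    A region is a maximal 8-connected plateau whose every outside neighbour
    is strictly lower; maxima are found on the whole opened image and then
    restricted to the mask, so a masked-in pixel shadowed by higher
    masked-out terrain never counts as a treetop.  Plateaus at or below zero
    height are background and are discarded.

    ``min_prominence`` (metres) switches to h-maxima: maxima standing less
    than this height above their surroundings are suppressed, which keeps a
    noisy apex from shattering into many one-pixel maxima.  Zero keeps the
    exact plateau definition.
    """
    mask = np.asarray(tree_mask, dtype=bool) & opened.valid
    if not mask.any():
        return []
    finite_min = float(opened.values[opened.valid].min())
    work = np.where(opened.valid, opened.values, min(finite_min, 0.0) - 1.0)
    if min_prominence > 0:
        maxima = h_maxima(work, min_prominence).astype(bool) & mask
    else:
        maxima = local_maxima(work, connectivity=2, allow_borders=True) & mask
    maxima &= opened.values > 0
    labels, n = ndimage.label(maxima, structure=np.ones((3, 3), dtype=int))
    regions = []
    ids = itertools.count(start_id)
    objects = ndimage.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        rr, cc = np.nonzero(labels[sl] == lab)
        regions.append(
            TreetopRegion(
                id=next(ids),
                rows=rr + sl[0].start,
                cols=cc + sl[1].start,
                scale=int(scale),
            )
        )
    return regions


def fit_gaussian_crown(chm: RasterGrid, region: TreetopRegion) -> GaussianCrownModel | None:
    """Least-squares fit of the Gaussian crown surface over the region pixels.

    Regions with fewer than 6 pixels cannot constrain the 5 parameters and
    are flagged degenerate (no model).  Initialization is deterministic: the
    apex at the region's CHM maximum, spreads from the region's second
    moments, sigma bounded between a quarter cell and the region diameter.
    """
    if region.n_pixels < N_PARAMS + 1:
        region.degenerate = True
        region.model = None
        return None
    cs = chm.cell_size
    x0, y0 = chm.origin
    xs = x0 + (region.cols + 0.5) * cs
    ys = y0 - (region.rows + 0.5) * cs
    z = chm.values[region.rows, region.cols]

    i_max = int(np.argmax(z))
    a0 = float(z[i_max])
    mx0, my0 = float(xs[i_max]), float(ys[i_max])
    extent = max(xs.max() - xs.min(), ys.max() - ys.min(), cs)
    sx0 = float(max(np.std(xs), 0.5 * cs))
    sy0 = float(max(np.std(ys), 0.5 * cs))

    lo_s, hi_s = 0.25 * cs, max(extent, 0.5 * cs) * 2.0
    p0 = [max(a0, 1e-6), mx0, my0, np.clip(sx0, lo_s, hi_s), np.clip(sy0, lo_s, hi_s)]
    bounds = (
        [1e-6, xs.min() - extent, ys.min() - extent, lo_s, lo_s],
        [max(2.0 * a0, 1.0), xs.max() + extent, ys.max() + extent, hi_s, hi_s],
    )

    def resid(p):
        A, mx, my, sx, sy = p
        return A * np.exp(-((xs - mx) ** 2 / (2 * sx**2) + (ys - my) ** 2 / (2 * sy**2))) - z

    sol = optimize.least_squares(resid, p0, bounds=bounds, method="trf", xtol=1e-12, ftol=1e-12)
    A, mx, my, sx, sy = sol.x
    eps2 = float(np.mean(sol.fun**2))
    model = GaussianCrownModel(
        A=float(A),
        mu_x=float(mx),
        mu_y=float(my),
        sigma_x=float(sx),
        sigma_y=float(sy),
        residual=eps2,
        n_pixels=region.n_pixels,
    )
    region.model = model
    region.degenerate = False
    return model


def _critical_or_ratio(
    F: float, df1: float, df2: float, alpha: float, critical_ratio: float | None
) -> bool:
    """True when the statistic is significant (one-sided, upper tail)."""
    if critical_ratio is not None:
        return F > critical_ratio
    if df1 <= 0 or df2 <= 0:
        return False
    return F > stats.f.ppf(1.0 - alpha, df1, df2)


def _shared_pixels(upper: TreetopRegion, lower: TreetopRegion, ncols: int = 1 << 20) -> int:
    return len(upper.flat_pixels(ncols) & lower.flat_pixels(ncols))


def residual_f_test(
    upper: TreetopRegion,
    lowers: list[TreetopRegion],
    alpha: float = 0.05,
    denominator: str = "sum",
    critical_ratio: float | None = None,
) -> str:
    """Gaussian-fit residual comparison across scales.

    F = eps^2(upper) / sum_k eps^2(lower_k); a significantly large F means
    the single upper-scale surface fits worse than the per-region lower-scale
    surfaces — the upper region straddles several crowns -> ``'keep_lower'``.
    Residuals that are all numerically perfect give ``'keep_upper'``.
    """
    if not lowers:
        raise ValueError("residual_f_test needs at least one lower region")
    eps_u = upper.model.residual
    eps_ls = [r.model.residual for r in lowers]
    if eps_u < RESIDUAL_TOL and sum(eps_ls) < RESIDUAL_TOL:
        return "keep_upper"
    m = len(lowers)
    denom = sum(eps_ls) if denominator == "sum" else sum(eps_ls) / m
    denom = max(denom, RESIDUAL_TOL * 1e-3)
    F = eps_u / denom
    df1 = upper.model.n_pixels - N_PARAMS
    df2 = sum(r.model.n_pixels for r in lowers) - N_PARAMS * m
    if critical_ratio is None and m == 1:
        # concentric case: the upper region usually contains the lower one, so
        # the two mean squared residuals share the noise of the common pixels.
        # Decomposing SSR(upper) into the shared part plus an independent
        # annulus gives F ~ (n_l/n_u) * (1 + chi2_a/chi2_l) under the null,
        # whose upper quantile replaces the naive F critical value.
        low = lowers[0]
        n_u, n_l = upper.n_pixels, low.n_pixels
        n_sh = _shared_pixels(upper, low)
        n_a = n_u - n_sh
        if n_sh > 0 and denominator == "sum":
            if n_a <= N_PARAMS or n_l <= N_PARAMS:
                return "keep_upper"
            fq = stats.f.ppf(1.0 - alpha, n_a - N_PARAMS, n_l - N_PARAMS)
            crit = (n_l / n_u) * (1.0 + (n_a - N_PARAMS) / (n_l - N_PARAMS) * fq)
            return "keep_lower" if F > crit else "keep_upper"
    return "keep_lower" if _critical_or_ratio(F, df1, df2, alpha, critical_ratio) else "keep_upper"


def intensity_f_test(
    upper: TreetopRegion,
    lowers: list[TreetopRegion],
    intensity_stack: np.ndarray,
    alpha: float = 0.05,
    denominator: str = "sum",
    critical_ratio: float | None = None,
) -> str:
    """Intensity-variance comparison across scales.

    F = sum_l s^2_l(upper) / sum_k sum_l s^2_l(lower_k) over the spectral
    channels; a significantly large F means the upper region mixes crowns of
    different spectral signatures -> ``'keep_lower'``.
    """
    if not lowers:
        raise ValueError("intensity_f_test needs at least one lower region")
    n_ch = intensity_stack.shape[0]
    if upper.intensity_variances is None:
        upper.compute_intensity_variances(intensity_stack)
    for r in lowers:
        if r.intensity_variances is None:
            r.compute_intensity_variances(intensity_stack)
    num = float(np.sum(upper.intensity_variances))
    m = len(lowers)
    den = float(sum(np.sum(r.intensity_variances) for r in lowers))
    if denominator == "mean":
        den /= m
    den = max(den, VARIANCE_FLOOR)
    F = num / den
    df1 = n_ch * (upper.n_pixels - 1)
    df2 = sum(n_ch * (r.n_pixels - 1) for r in lowers)
    if critical_ratio is None and m == 1:
        # same nesting correction as the residual test: the shared pixels make
        # s2(upper) ~ w * s2(lower) + (1-w) * s2(annulus) under the null
        low = lowers[0]
        n_u, n_l = upper.n_pixels, low.n_pixels
        n_sh = _shared_pixels(upper, low)
        n_a = n_u - n_sh
        if n_sh > 0 and denominator == "sum":
            if n_a < 2 or n_l < 2:
                return "keep_upper"
            w = (n_sh - 1) / max(n_u - 1, 1)
            fq = stats.f.ppf(1.0 - alpha, n_ch * (n_a - 1), n_ch * (n_l - 1))
            crit = w + (1.0 - w) * fq
            return "keep_lower" if F > crit else "keep_upper"
    return "keep_lower" if _critical_or_ratio(F, df1, df2, alpha, critical_ratio) else "keep_upper"


def merge_across_scales(
    chm: RasterGrid,
    intensity_stack: np.ndarray | None,
    tree_mask: np.ndarray,
    scales: list[int],
    alpha: float = 0.05,
    denominator: str = "sum",
    critical_ratio: float | None = None,
    min_prominence: float = 0.0,
) -> list[TreetopRegion]:
    """Detect treetop regions at each scale and merge them bottom-up.

    Starting from the lowest scale's regions, each upper-scale region either
    joins the current set (no overlap), or challenges the current regions it
    overlaps: if either F-test is significant the lower regions stay,
    otherwise the upper region replaces them (the concentric single-crown
    case, where the larger cross-section is kept).  Degenerate regions
    (too few pixels to fit) always lose to a fitted competitor; among
    degenerates the lower scale wins.

    The returned regions are pairwise pixel-disjoint.
    """
    if not scales:
        raise ValueError("merge_across_scales needs at least one scale")
    scales = sorted(int(s) for s in scales)
    nrows, ncols = chm.shape

    def detect(scale: int, start_id: int) -> list[TreetopRegion]:
        opened = grayscale_open(chm, disk_structuring_element(scale))
        regs = extract_treetop_regions(
            opened, tree_mask, scale, start_id=start_id, min_prominence=min_prominence
        )
        for r in regs:
            fit_gaussian_crown(chm, r)
            if intensity_stack is not None:
                r.compute_intensity_variances(intensity_stack)
        return regs

    next_id = 1
    current = detect(scales[0], next_id)
    next_id += len(current) + 1
    for scale in scales[1:]:
        uppers = detect(scale, next_id)
        next_id += len(uppers) + 1
        cur_label = np.zeros((nrows, ncols), dtype=np.int64)
        for idx, r in enumerate(current, start=1):
            cur_label[r.rows, r.cols] = idx
        keep = [True] * len(current)
        added: list[TreetopRegion] = []
        for up in uppers:
            hit = np.unique(cur_label[up.rows, up.cols])
            hit = hit[hit > 0]
            lowers = [current[i - 1] for i in hit if keep[i - 1]]
            if not lowers:
                added.append(up)
                continue
            decision = _decide(up, lowers, intensity_stack, alpha, denominator, critical_ratio)
            if decision == "keep_upper":
                for low in lowers:
                    keep[current.index(low)] = False
                added.append(up)
        current = [r for r, k in zip(current, keep) if k] + added
    log.info("merge_across_scales: %d treetop regions from scales %s", len(current), scales)
    return current


def _decide(
    upper: TreetopRegion,
    lowers: list[TreetopRegion],
    intensity_stack: np.ndarray | None,
    alpha: float,
    denominator: str,
    critical_ratio: float | None,
) -> str:
    fitted_lowers = [r for r in lowers if not r.degenerate]
    if upper.degenerate and fitted_lowers:
        return "keep_lower"
    if upper.degenerate and not fitted_lowers:
        return "keep_lower"  # tie between degenerates: conservative, keep lower scale
    if not fitted_lowers:
        return "keep_upper"  # fitted upper beats degenerate lowers
    if (
        residual_f_test(upper, fitted_lowers, alpha, denominator, critical_ratio)
        == "keep_lower"
    ):
        return "keep_lower"
    if intensity_stack is not None:
        if (
            intensity_f_test(
                upper, fitted_lowers, intensity_stack, alpha, denominator, critical_ratio
            )
            == "keep_lower"
        ):
            return "keep_lower"
    return "keep_upper"


def disk_seeds_from_centres(
    centres: list[tuple[float, float, float]],
    grid: RasterGrid,
    tree_mask: np.ndarray | None = None,
    radius_px: int = 5,
) -> list[TreetopRegion]:
    """Disk seed regions around known treetop centres (reference-seed runs).

    Each centre becomes a disk of ``radius_px`` pixels clipped to the grid
    (and the tree mask, when given); used to measure how much delineation
    accuracy depends on seed quality rather than on the growing criterion.
    """
    nrows, ncols = grid.shape
    if tree_mask is None:
        tree_mask = np.ones((nrows, ncols), dtype=bool)
    taken = np.zeros((nrows, ncols), dtype=bool)
    seeds = []
    for k, (x, y, _apex) in enumerate(centres, start=1):
        r0, c0 = grid.world_to_cell(x, y)
        rr, cc = np.mgrid[
            max(0, r0 - radius_px) : min(nrows, r0 + radius_px + 1),
            max(0, c0 - radius_px) : min(ncols, c0 + radius_px + 1),
        ]
        inside = ((rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px**2) & tree_mask[rr, cc]
        inside &= ~taken[rr, cc]
        if not inside.any():
            continue
        rows, cols = rr[inside], cc[inside]
        taken[rows, cols] = True
        seeds.append(TreetopRegion(id=k, rows=rows, cols=cols, scale=2 * radius_px + 1))
    return seeds
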