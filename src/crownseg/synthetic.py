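"""Synthetic multispectral LiDAR forest scenes with exported ground truth.

The generator emulates a three-channel (1550/1064/532 nm) airborne LiDAR
acquisition over a deciduous scene at 0.25 m cells: crowns are truncated
Gaussian caps of mixed diameters and heights, optionally overlapping in
woodlot-like clusters; channel intensities follow vegetation-like spectra
(1064 nm bright, 532 nm dark inside crowns, reversed on background) so that
NDVI-based masking behaves as it would on real data.

Conventions
-----------
The nominal crown diameter is the +/-2 sigma width of the Gaussian profile
(D = 4 sigma).  The crown support — where the cap exceeds 5 % of the apex
height, giving a finite ground-truth polygon — extends to ~1.22 D.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from shapely.geometry import Point, Polygon

from . import io as cio
from .raster import RasterGrid
from .scene import TITAN_WAVELENGTHS, MultiChannelScene, PointCloud

__all__ = [
    "SyntheticSceneSpec",
    "CrownSpec",
    "GroundTruth",
    "generate_scene",
    "sample_point_cloud",
    "write_ground_truth",
    "read_ground_truth",
]

#: Crown support is cut where the cap falls below this fraction of apex height.
SUPPORT_CUTOFF = 0.05
#: Support radius in sigma units: exp(-r^2 / 2 sigma^2) = 0.05.
SUPPORT_RADIUS_SIGMA = float(np.sqrt(-2.0 * np.log(SUPPORT_CUTOFF)))  # ~2.448
#: Nominal diameter convention: D = 4 sigma.
DIAMETER_SIGMA = 4.0


@dataclass(frozen=True)
class SyntheticSceneSpec:
    """Generative description of a synthetic forest scene.

    Defaults emulate a mature deciduous stand under a three-channel survey:
    ~0.25 m cells, ~45 first-return points per m^2 and channel, crowns 3-7 m
    across and 20-30 m tall, vegetation-like intensity spectra.
    """

    extent: tuple[float, float] = (60.0, 60.0)
    cell_size: float = 0.25
    n_trees: int = 25
    crown_diameter_range: tuple[float, float] = (3.0, 7.0)
    diameter_classes: int = 3
    crown_height_range: tuple[float, float] = (20.0, 30.0)
    overlap_fraction: float = 0.0
    crown_intensity_means: tuple[float, ...] = (40.0, 120.0, 30.0)
    tree_mean_sd: float = 15.0
    intensity_noise_sd: float = 0.0
    background_intensity_means: tuple[float, ...] = (30.0, 20.0, 60.0)
    chm_noise_sd: float = 0.0
    chm_texture_sd: float = 0.0
    chm_texture_scale: float = 1.0
    point_density: float = 45.0
    rng_seed: int = 0
    channel_wavelengths: tuple[float, ...] = TITAN_WAVELENGTHS

    def __post_init__(self) -> None:
        if self.n_trees < 0:
            raise ValueError("n_trees must be non-negative")
        if min(self.crown_diameter_range) <= 0 or min(self.crown_height_range) <= 0:
            raise ValueError("crown diameters and heights must be positive")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if len(self.crown_intensity_means) != len(self.background_intensity_means):
            raise ValueError("channel mean tuples must have equal length")

    def with_seed(self, seed: int) -> "SyntheticSceneSpec":
        return replace(self, rng_seed=int(seed))


@dataclass(frozen=True)
class CrownSpec:
    """One planted crown: geometry plus per-channel mean intensities."""

    x: float
    y: float
    apex: float
    sigma: float
    channel_means: tuple[float, ...]

    @property
    def support_radius(self) -> float:
        return SUPPORT_RADIUS_SIGMA * self.sigma

    def surface(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Crown height surface at world coordinates (0 outside support)."""
        d2 = (np.asarray(x) - self.x) ** 2 + (np.asarray(y) - self.y) ** 2
        z = self.apex * np.exp(-d2 / (2.0 * self.sigma**2))
        return np.where(d2 <= self.support_radius**2, z, 0.0)


@dataclass
class GroundTruth:
    """Reference crowns for a synthetic scene.

    ``label_map`` holds 0 for background and k for crown k (1-based, the
    index into ``trees`` + 1); contested pixels belong to the taller crown
    surface, mirroring what an overhead CHM records.
    """

    label_map: RasterGrid
    treetop_centres: list[tuple[float, float, float]]
    crown_polygons: list[Polygon]
    trees: list[CrownSpec] = field(default_factory=list)

    @property
    def n_crowns(self) -> int:
        return len(self.treetop_centres)

    @property
    def labels(self) -> np.ndarray:
        return self.label_map.values.astype(int)


def _place_crowns(spec: SyntheticSceneSpec, rng: np.random.Generator) -> list[CrownSpec]:
    """Sample crown positions, sizes and spectra under the overlap target."""
    w, h = spec.extent
    n = spec.n_trees
    n_overlap = int(round(spec.overlap_fraction * n)) if n > 1 else 0
    crowns: list[CrownSpec] = []
    max_tries = 2000

    def sample_size() -> tuple[float, float]:
        # diameter_classes > 0 emulates scenes with a few predominant crown
        # sizes (street/woodlot stands); 0 draws continuously from the range
        lo, hi = spec.crown_diameter_range
        if spec.diameter_classes > 0:
            classes = np.linspace(lo, hi, max(spec.diameter_classes, 1))
            d = float(rng.choice(classes))
        else:
            d = rng.uniform(lo, hi)
        apex = rng.uniform(*spec.crown_height_range)
        return d / DIAMETER_SIGMA, apex

    def sample_means() -> tuple[float, ...]:
        offs = rng.normal(0.0, spec.tree_mean_sd, size=len(spec.crown_intensity_means))
        return tuple(float(max(m + o, 1.0)) for m, o in zip(spec.crown_intensity_means, offs))

    sizes = [sample_size() for _ in range(n)]
    spectra = [sample_means() for _ in range(n)]
    # place isolated crowns largest-first (packs far more reliably), then the
    # overlap-attached ones
    iso = sorted(range(n - n_overlap), key=lambda i: -sizes[i][0])
    order = iso + list(range(n - n_overlap, n))
    for k in order:
        sigma, apex = sizes[k]
        means = spectra[k]
        r = SUPPORT_RADIUS_SIGMA * sigma
        attach = k >= n - n_overlap and crowns
        placed = False
        for _ in range(max_tries):
            if attach:
                host = crowns[int(rng.integers(len(crowns)))]
                sep = rng.uniform(0.5, 0.8) * (host.support_radius + r)
                theta = rng.uniform(0.0, 2.0 * np.pi)
                cx = host.x + sep * np.cos(theta)
                cy = host.y + sep * np.sin(theta)
                if not (r <= cx <= w - r and r <= cy <= h - r):
                    continue
                ok = True
            else:
                if w - 2 * r <= 0 or h - 2 * r <= 0:
                    raise ValueError(
                        "scene extent too small for the requested crown sizes"
                    )
                cx = rng.uniform(r, w - r)
                cy = rng.uniform(r, h - r)
                ok = all(
                    np.hypot(cx - c.x, cy - c.y) > r + c.support_radius for c in crowns
                )
            if ok:
                crowns.append(CrownSpec(cx, cy, apex, sigma, means))
                placed = True
                break
        if not placed:
            raise ValueError(
                "could not place crown %d under the overlap/packing constraint "
                "(n_trees=%d, overlap_fraction=%.2f, extent=%s)"
                % (k, n, spec.overlap_fraction, spec.extent)
            )
    return crowns


def generate_scene(spec: SyntheticSceneSpec) -> tuple[MultiChannelScene, GroundTruth]:
    """Generate a scene and its ground truth; identical spec+seed reproduce bit-identically.

    The CHM is the per-pixel maximum over truncated Gaussian caps plus a zero
    ground plane plus optional Gaussian noise.  Each tree pixel is labelled by
    the crown whose surface attains the maximum there; channel intensities are
    the owning tree's channel mean (background means elsewhere) plus noise.
    """
    seed = spec.rng_seed
    rng_geom = np.random.default_rng([seed, 101])
    rng_chm = np.random.default_rng([seed, 202])
    rng_int = np.random.default_rng([seed, 303])

    w, h = spec.extent
    cs = spec.cell_size
    ncols = int(round(w / cs))
    nrows = int(round(h / cs))
    origin = (0.0, float(h))
    carrier = RasterGrid(np.zeros((nrows, ncols)), cs, origin)
    X, Y = carrier.cell_centers()

    crowns = _place_crowns(spec, rng_geom) if spec.n_trees else []

    chm = np.zeros((nrows, ncols))
    labels = np.zeros((nrows, ncols), dtype=np.int64)
    for k, crown in enumerate(crowns, start=1):
        z = crown.surface(X, Y)
        take = z > chm
        chm[take] = z[take]
        labels[take] = k

    if spec.chm_texture_sd > 0:
        # branch-scale canopy texture: spatially correlated bumps inside
        # crowns, absent from the smooth ground
        from scipy.ndimage import gaussian_filter

        white = rng_chm.normal(0.0, 1.0, chm.shape)
        corr = gaussian_filter(white, spec.chm_texture_scale / cs, mode="wrap")
        corr *= spec.chm_texture_sd / max(corr.std(), 1e-12)
        chm = np.where(labels > 0, np.maximum(chm + corr, 0.0), chm)
    if spec.chm_noise_sd > 0:
        chm = np.maximum(chm + rng_chm.normal(0.0, spec.chm_noise_sd, chm.shape), 0.0)

    bands = []
    for c in range(len(spec.crown_intensity_means)):
        vals = np.full((nrows, ncols), spec.background_intensity_means[c])
        for k, crown in enumerate(crowns, start=1):
            vals[labels == k] = crown.channel_means[c]
        if spec.intensity_noise_sd > 0:
            vals = vals + rng_int.normal(0.0, spec.intensity_noise_sd, vals.shape)
        bands.append(RasterGrid(np.maximum(vals, 0.0), cs, origin))

    scene = MultiChannelScene(
        chm=RasterGrid(chm, cs, origin),
        intensity=bands,
        channel_wavelengths=spec.channel_wavelengths,
        tree_mask=labels > 0,
    )
    truth = GroundTruth(
        label_map=RasterGrid(labels.astype(float), cs, origin),
        treetop_centres=[(c.x, c.y, c.apex) for c in crowns],
        crown_polygons=[Point(c.x, c.y).buffer(c.support_radius, quad_segs=32) for c in crowns],
        trees=crowns,
    )
    return scene, truth


def analytic_surface(
    truth: GroundTruth, x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free canopy surface and owning crown (0 = ground) at world points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.zeros_like(x)
    owner = np.zeros(x.shape, dtype=np.int64)
    for k, crown in enumerate(truth.trees, start=1):
        zk = crown.surface(x, y)
        take = zk > z
        z[take] = zk[take]
        owner[take] = k
    return z, owner


def sample_point_cloud(
    scene: MultiChannelScene,
    truth: GroundTruth,
    density: float = 45.0,
    seed: int = 0,
    chm_noise_sd: float = 0.0,
    intensity_noise_sd: float = 0.0,
    background_means: tuple[float, ...] = (30.0, 20.0, 60.0),
) -> PointCloud:
    """Sample first-return LiDAR points over the scene, one cloud per channel.

    Each channel is an independent homogeneous planar Poisson process of the
    given density (points/m^2).  A point's z is the analytic surface height at
    its position plus optional noise; its intensity is drawn from the owning
    crown's channel model (or the background model).  All points are first
    returns.
    """
    if density <= 0:
        raise ValueError("point density must be positive")
    rng = np.random.default_rng([int(seed), 404])
    cs = scene.chm.cell_size
    nrows, ncols = scene.chm.shape
    w = ncols * cs
    h = nrows * cs
    area = w * h
    x0, y0 = scene.chm.origin

    cols: dict[str, list[np.ndarray]] = {k: [] for k in PointCloud.FIELDS}
    for c in range(scene.n_channels):
        n = int(rng.poisson(density * area))
        px = x0 + rng.uniform(0.0, w, size=n)
        py = y0 - rng.uniform(0.0, h, size=n)
        z, owner = analytic_surface(truth, px, py)
        if chm_noise_sd > 0:
            z = np.maximum(z + rng.normal(0.0, chm_noise_sd, size=n), 0.0)
        mean = np.full(n, background_means[c] if c < len(background_means) else 0.0)
        for k, crown in enumerate(truth.trees, start=1):
            mean[owner == k] = crown.channel_means[c]
        inten = mean
        if intensity_noise_sd > 0:
            inten = inten + rng.normal(0.0, intensity_noise_sd, size=n)
        cols["x"].append(px)
        cols["y"].append(py)
        cols["z"].append(z)
        cols["intensity"].append(np.maximum(inten, 0.0))
        cols["channel"].append(np.full(n, c + 1, dtype=int))
        cols["return_number"].append(np.ones(n, dtype=int))

    return PointCloud(*(np.concatenate(cols[k]) if cols[k] else np.array([]) for k in PointCloud.FIELDS))


def write_ground_truth(truth: GroundTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write ground truth: label map (TIFF), polygons and centres (GeoJSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "label_map": out / "truth_labels.tif",
        "crowns": out / "truth_crowns.geojson",
        "treetops": out / "truth_treetops.geojson",
    }
    cio.write_label_raster(paths["label_map"], truth.labels, truth.label_map)
    cio.write_geojson(
        paths["crowns"],
        [
            {"geometry": poly, "properties": {"label": k + 1}}
            for k, poly in enumerate(truth.crown_polygons)
        ],
    )
    cio.write_geojson(
        paths["treetops"],
        [
            {"geometry": Point(x, y), "properties": {"label": k + 1, "apex_height": z}}
            for k, (x, y, z) in enumerate(truth.treetop_centres)
        ],
    )
    return paths


def read_ground_truth(out_dir: str | Path) -> GroundTruth:
    out = Path(out_dir)
    labels, carrier = cio.read_label_raster(out / "truth_labels.tif")
    crowns = cio.read_geojson(out / "truth_crowns.geojson")
    tops = cio.read_geojson(out / "truth_treetops.geojson")
    centres = [
        (f["geometry"].x, f["geometry"].y, f["properties"]["apex_height"]) for f in tops
    ]
    polys = [f["geometry"] for f in crowns]
    return GroundTruth(
        label_map=RasterGrid(labels.astype(float), carrier.cell_size, carrier.origin),
        treetop_centres=centres,
        crown_polygons=polys,
    )
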