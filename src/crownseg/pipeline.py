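"""End-to-end orchestration: preprocess -> scales -> treetops -> crowns -> report.

A :class:`PipelineConfig` gathers every tunable of the method; ``run_pipeline``
executes the full chain on a scene (or generates one from a synthetic spec),
writes all intermediates into a run directory, and returns the in-memory
results.  Identical config + seed produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Point, box

from . import io as cio
from .evaluate import MatchReport, categorize_matches
from .neutrosophic import NeutrosophicParams, grow_crowns
from .preprocess import build_tree_mask, compute_ndvi, gaussian_smooth_3x3
from .raster import RasterGrid
from .scene import MultiChannelScene
from .scales import mean_difference_curve, select_dominant_scales
from .synthetic import GroundTruth
from .treetops import TreetopRegion, disk_seeds_from_centres, merge_across_scales
from .watershed import fuse_surfaces, mcw_segment

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "export_crowns_vector", "rasterize_crown_features"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved parameters of a full delineation run."""

    # preprocessing
    ndvi_thresh: float = 0.25
    height_thresh: float = 4.0
    mask_mode: str = "conjunctive"
    mask_clean: bool = True
    smooth_sigma: float = 0.8
    # scale analysis
    d_start: int = 3
    d_end: int = 73
    d_step: int = 2
    d_min: int = 5
    d_max: int = 31
    prominence: float = 0.05
    scales_override: list[int] | None = None
    include_d_min: bool = True
    # treetop merging
    alpha: float = 0.05
    f_denominator: str = "sum"
    critical_ratio: float | None = None
    peak_prominence: float = 0.2
    # segmentation
    source: str = "both"
    tau_h: float = 1.0
    fill: bool = True
    indeterminacy_cut: float = 0.5
    fixed_truth_cut: float = 0.6
    sigmoid_a: tuple[float, float, float] = (1.0, 1.0, 4.5)
    variance_scale: float = 100.0
    # MCW baseline
    mcw_relief: str = "gradient"
    # reference seeding
    seed_radius_px: int = 5
    use_reference_seeds: bool = False
    # synthetic runs
    rng_seed: int = 0

    def neutrosophic_params(self) -> NeutrosophicParams:
        a1, a2, a3 = self.sigmoid_a
        return NeutrosophicParams(
            indeterminacy_cut=self.indeterminacy_cut,
            fixed_truth_cut=self.fixed_truth_cut,
            a1=a1,
            a2=a2,
            a3=a3,
            variance_scale=self.variance_scale,
            tau_h=self.tau_h,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sigmoid_a"] = list(self.sigmoid_a)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in data.items() if k in known}
        if "sigmoid_a" in kwargs:
            kwargs["sigmoid_a"] = tuple(kwargs["sigmoid_a"])
        return cls(**kwargs)


@dataclass
class PipelineResult:
    config: PipelineConfig
    scene: MultiChannelScene
    tree_mask: np.ndarray
    scales: list[int]
    treetops: list[TreetopRegion]
    labels: dict[str, np.ndarray] = field(default_factory=dict)
    reports: dict[str, MatchReport] = field(default_factory=dict)
    run_dir: Path | None = None


def run_pipeline(
    config: PipelineConfig,
    scene: MultiChannelScene,
    truth: GroundTruth | None = None,
    out_dir: str | Path | None = None,
    methods: tuple[str, ...] = ("neutrosophic", "mcw"),
) -> PipelineResult:
    """Run the full delineation chain on a preprocessed scene.

    Stages: vegetation masking, CHM smoothing, scale-curve analysis,
    multi-scale treetop detection and merging, crown segmentation by the
    requested methods, and (when ground truth is supplied) overlap
    evaluation.  All intermediates are written under ``out_dir`` when given.
    """
    stage = "preprocess"
    log_handler = None
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        log_handler = logging.FileHandler(Path(out_dir) / "run.log", mode="w")
        log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
        log_handler.setLevel(logging.INFO)
        pkg_logger = logging.getLogger("crownseg")
        pkg_logger.addHandler(log_handler)
        if pkg_logger.level in (logging.NOTSET, logging.WARNING):
            pkg_logger.setLevel(logging.INFO)
    try:
        nir = scene.intensity[scene.channel_index(1064.0)]
        green = scene.intensity[scene.channel_index(532.0)]
        ndvi = compute_ndvi(nir, green)
        chm_s = gaussian_smooth_3x3(scene.chm, config.smooth_sigma)
        tree_mask = build_tree_mask(
            chm_s, ndvi, config.ndvi_thresh, config.height_thresh, config.mask_mode
        )
        if config.mask_clean:
            # speckle from per-pixel NDVI noise: close pinholes, drop islands
            se = np.ones((3, 3), dtype=bool)
            tree_mask = ndimage.binary_opening(
                ndimage.binary_closing(tree_mask, structure=se), structure=se
            )
        log.info("preprocess: %d tree pixels", int(tree_mask.sum()))
        working = MultiChannelScene(
            chm=chm_s,
            intensity=scene.intensity,
            channel_wavelengths=scene.channel_wavelengths,
            tree_mask=tree_mask,
        )

        stage = "scale_analysis"
        if config.scales_override:
            scales = [int(s) for s in config.scales_override]
            curve = None
        else:
            curve = mean_difference_curve(
                chm_s, tree_mask, config.d_start, config.d_end, config.d_step
            )
            scales = select_dominant_scales(curve, config.d_min, config.d_max, config.prominence)
            if config.include_d_min and config.d_min not in scales:
                # the smallest dominant crown scale matters most: detections it
                # adds inside larger crowns are pruned by the cross-scale merge,
                # while genuinely small crowns are only visible here
                scales = [config.d_min, *scales]
            if not scales:
                scales = [config.d_min]
        log.info("scale_analysis: dominant scales %s", scales)

        stage = "treetop_detection"
        stack = working.intensity_stack()
        treetops = merge_across_scales(
            chm_s,
            stack,
            tree_mask,
            scales,
            alpha=config.alpha,
            denominator=config.f_denominator,
            critical_ratio=config.critical_ratio,
            min_prominence=config.peak_prominence,
        )

        stage = "seeding"
        if config.use_reference_seeds:
            if truth is None:
                raise ValueError("reference seeding requested but no ground truth given")
            seeds = disk_seeds_from_centres(
                truth.treetop_centres, chm_s, tree_mask, config.seed_radius_px
            )
        else:
            seeds = treetops

        result = PipelineResult(
            config=config, scene=working, tree_mask=tree_mask, scales=scales, treetops=treetops
        )

        stage = "segmentation"
        if "neutrosophic" in methods:
            result.labels["neutrosophic"] = grow_crowns(
                working,
                seeds,
                config.neutrosophic_params(),
                source=config.source,
                fill=config.fill,
            )
        if "mcw" in methods:
            sources: list[RasterGrid]
            if config.source == "chm":
                sources = [chm_s]
            elif config.source == "intensity":
                sources = list(working.intensity)
            else:
                sources = [chm_s, *working.intensity]
            surface = fuse_surfaces(sources, tree_mask, relief=config.mcw_relief)
            result.labels["mcw"] = mcw_segment(surface, seeds, tree_mask)

        stage = "evaluation"
        if truth is not None and truth.n_crowns:
            for name, labels in result.labels.items():
                result.reports[name] = categorize_matches(labels, truth.labels)

        stage = "write"
        if out_dir is not None:
            result.run_dir = _write_run(Path(out_dir), result, curve, truth, ndvi)
        return result
    except Exception as exc:
        log.error("pipeline failed at stage %r: %s (config=%s)", stage, exc, config.to_dict())
        raise
    finally:
        if log_handler is not None:
            logging.getLogger("crownseg").removeHandler(log_handler)
            log_handler.close()


def _write_run(out: Path, result: PipelineResult, curve, truth, ndvi=None) -> Path:
    out.mkdir(parents=True, exist_ok=True)
    cio.dump_config_file(out / "config.yaml", result.config.to_dict())
    cio.write_raster(out / "chm_smoothed.tif", result.scene.chm)
    if ndvi is not None:
        cio.write_raster(out / "ndvi.tif", ndvi)
    cio.write_label_raster(
        out / "tree_mask.tif", result.tree_mask.astype(np.int32), result.scene.chm
    )
    if curve is not None:
        import pandas as pd

        pd.DataFrame(
            {
                "diameter": curve.diameters,
                "mean": curve.means,
                "difference": np.r_[np.nan, curve.differences],
            }
        ).to_csv(out / "scale_curve.csv", index=False)
    (out / "scales.json").write_text(json.dumps({"scales": result.scales}))

    tops = []
    for r in result.treetops:
        props = {"id": r.id, "scale": r.scale, "n_pixels": r.n_pixels}
        if r.model is not None:
            props.update(
                {
                    "apex": r.model.A,
                    "sigma_x": r.model.sigma_x,
                    "sigma_y": r.model.sigma_y,
                    "residual": r.model.residual,
                }
            )
            geom = Point(r.model.mu_x, r.model.mu_y)
        else:
            cs = result.scene.chm.cell_size
            x0, y0 = result.scene.chm.origin
            geom = Point(x0 + (r.cols.mean() + 0.5) * cs, y0 - (r.rows.mean() + 0.5) * cs)
        tops.append({"geometry": geom, "properties": props})
    cio.write_geojson(out / "treetops.geojson", tops)

    for name, labels in result.labels.items():
        cio.write_label_raster(out / f"crowns_{name}.tif", labels, result.scene.chm)
        cio.write_geojson(
            out / f"crowns_{name}.geojson",
            export_crowns_vector(labels, result.scene.chm),
        )
    if result.reports:
        (out / "match_report.json").write_text(
            json.dumps({k: v.to_dict() for k, v in result.reports.items()}, indent=1)
        )
    return out


def export_crowns_vector(
    labels: np.ndarray, grid: RasterGrid, fill_holes: bool = True
) -> list[dict]:
    """One polygon feature per crown label, with pixel and metric areas.

    Interior holes are filled by default (crowns are simply connected);
    ``fill_holes=False`` keeps the raw pixel geometry.
    """
    labels = np.asarray(labels)
    feats = []
    cs = grid.cell_size
    x0, y0 = grid.origin
    for lab in np.unique(labels[labels > 0]):
        m = labels == lab
        if fill_holes:
            m = ndimage.binary_fill_holes(m)
        rows, cols = np.nonzero(m)
        cells = [
            box(x0 + c * cs, y0 - (r + 1) * cs, x0 + (c + 1) * cs, y0 - r * cs)
            for r, c in zip(rows, cols)
        ]
        poly = shapely.union_all(cells)
        feats.append(
            {
                "geometry": poly,
                "properties": {
                    "label": int(lab),
                    "n_pixels": int(len(rows)),
                    "area_m2": float(len(rows) * cs * cs),
                },
            }
        )
    return feats


def rasterize_crown_features(features: list[dict], grid: RasterGrid) -> np.ndarray:
    """Rasterize crown polygon features back onto the grid by cell-centre test."""
    out = np.zeros(grid.shape, dtype=np.int64)
    X, Y = grid.cell_centers()
    for f in features:
        geom = f["geometry"]
        lab = f["properties"]["label"]
        inside = shapely.contains_xy(geom, X.ravel(), Y.ravel()).reshape(grid.shape)
        out[inside] = lab
    return out
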