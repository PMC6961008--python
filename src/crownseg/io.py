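"""File formats: TIFF rasters, GeoJSON vectors, CSV point clouds, YAML config.

Rasters are single-band float32 (or int32 for label maps) TIFF files; the
grid georeferencing (cell size, upper-left origin, nodata convention) rides
in the TIFF ImageDescription tag as JSON, so a written raster reloads to an
identical :class:`~crownseg.raster.RasterGrid`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import mapping, shape

from .raster import RasterGrid
from .scene import PointCloud

__all__ = [
    "write_raster",
    "read_raster",
    "write_label_raster",
    "read_label_raster",
    "write_geojson",
    "read_geojson",
    "write_points_csv",
    "read_points_csv",
    "load_config_file",
    "dump_config_file",
]

POINT_COLUMNS = ["x", "y", "z", "intensity", "channel", "return_number"]


def _describe(grid: RasterGrid, kind: str) -> str:
    return json.dumps(
        {
            "crownseg": {
                "kind": kind,
                "cell_size": grid.cell_size,
                "origin": list(grid.origin),
            }
        }
    )


def write_raster(path: str | Path, grid: RasterGrid) -> None:
    """Write a float raster as single-band float32 TIFF (nodata -> NaN)."""
    data = grid.values.astype(np.float32)
    data[grid.nodata_mask] = np.nan
    tifffile.imwrite(str(path), data, description=_describe(grid, "float"))


def read_raster(path: str | Path) -> RasterGrid:
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray().astype(float)
        meta = _read_meta(tif)
    nodata = ~np.isfinite(data)
    data = np.where(nodata, 0.0, data)
    return RasterGrid(data, meta["cell_size"], tuple(meta["origin"]), nodata)


def write_label_raster(path: str | Path, labels: np.ndarray, grid_like: RasterGrid) -> None:
    """Write an integer label map (0 = background) as int32 TIFF."""
    tifffile.imwrite(
        str(path), np.asarray(labels, dtype=np.int32), description=_describe(grid_like, "labels")
    )


def read_label_raster(path: str | Path) -> tuple[np.ndarray, RasterGrid]:
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray().astype(np.int64)
        meta = _read_meta(tif)
    carrier = RasterGrid(
        data.astype(float), meta["cell_size"], tuple(meta["origin"]), np.zeros(data.shape, bool)
    )
    return data, carrier


def _read_meta(tif: "tifffile.TiffFile") -> dict:
    desc = tif.pages[0].tags.get("ImageDescription")
    if desc is None:
        return {"cell_size": 1.0, "origin": [0.0, 0.0]}
    try:
        return json.loads(desc.value)["crownseg"]
    except (json.JSONDecodeError, KeyError):
        return {"cell_size": 1.0, "origin": [0.0, 0.0]}


# -- vectors ---------------------------------------------------------------


def write_geojson(path: str | Path, features: list[dict]) -> None:
    """Write a list of {'geometry': shapely geom, 'properties': dict} features."""
    collection = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(f["geometry"]) if f["geometry"] is not None else None,
                "properties": f.get("properties", {}),
            }
            for f in features
        ],
    }
    Path(path).write_text(json.dumps(collection, indent=1))


def read_geojson(path: str | Path) -> list[dict]:
    collection = json.loads(Path(path).read_text())
    return [
        {
            "geometry": shape(f["geometry"]) if f["geometry"] is not None else None,
            "properties": f.get("properties", {}),
        }
        for f in collection.get("features", [])
    ]


# -- point clouds ----------------------------------------------------------


def write_points_csv(path: str | Path, cloud: PointCloud) -> None:
    df = pd.DataFrame({c: getattr(cloud, c) for c in POINT_COLUMNS})
    df.to_csv(path, index=False)


def read_points_csv(path: str | Path) -> PointCloud:
    df = pd.read_csv(path)
    missing = [c for c in POINT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"point CSV missing columns: {missing}")
    return PointCloud(*(df[c].to_numpy() for c in POINT_COLUMNS))


# -- config ----------------------------------------------------------------


def load_config_file(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def dump_config_file(path: str | Path, config: dict) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))
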