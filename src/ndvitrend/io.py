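"""File I/O: TIFF rasters with JSON sidecar metadata, GeoJSON vectors,
CSV polygon-series matrices.

Rasters are written as plain (multi-band) TIFF with the grid geometry,
nodata sentinel, kind, time axis and category map serialized into the
ImageDescription tag as JSON, so write -> read round-trips values, mask
and geometry bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile

from .grid import Grid, PolygonSeriesMatrix, RasterLayer, RasterStack, VectorLayer

__all__ = [
    "read_raster",
    "write_raster",
    "read_vector",
    "write_vector",
    "read_series",
    "write_series",
]

_FORMAT_TAG = "ndvitrend-raster"


def _grid_meta(grid: Grid) -> dict:
    return {
        "n_rows": grid.n_rows,
        "n_cols": grid.n_cols,
        "cell_size": grid.cell_size,
        "origin": list(grid.origin),
    }


def _grid_from_meta(meta: dict) -> Grid:
    return Grid(
        n_rows=int(meta["n_rows"]),
        n_cols=int(meta["n_cols"]),
        cell_size=float(meta["cell_size"]),
        origin=tuple(meta["origin"]),
    )


def write_raster(obj: RasterLayer | RasterStack, path: str | Path) -> Path:
    """Write a layer or stack to a (multi-band) TIFF; returns the path."""
    path = Path(path)
    if isinstance(obj, RasterLayer):
        meta = {
            "format": _FORMAT_TAG,
            "class": "RasterLayer",
            "grid": _grid_meta(obj.grid),
            "kind": obj.kind,
            "nodata": None if _is_nan(obj.nodata) else obj.nodata,
            "categories": (
                {str(k): v for k, v in obj.categories.items()}
                if obj.categories
                else None
            ),
        }
        data = obj.values
    elif isinstance(obj, RasterStack):
        meta = {
            "format": _FORMAT_TAG,
            "class": "RasterStack",
            "grid": _grid_meta(obj.grid),
            "time_axis": [list(t) for t in obj.time_axis],
        }
        data = obj.values
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    tifffile.imwrite(
        path, data, description=json.dumps(meta), photometric="minisblack"
    )
    return path


def read_raster(path: str | Path) -> RasterLayer | RasterStack:
    """Read a raster written by :func:`write_raster`."""
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            desc = tif.pages[0].description
            data = tif.asarray()
    except (tifffile.TiffFileError, FileNotFoundError) as exc:
        raise IOError(f"unreadable raster file {path}: {exc}") from exc
    try:
        meta = json.loads(desc)
        assert meta.get("format") == _FORMAT_TAG
    except (json.JSONDecodeError, TypeError, AssertionError) as exc:
        raise IOError(f"{path} is not an ndvitrend raster (missing metadata)") from exc

    grid = _grid_from_meta(meta["grid"])
    if meta["class"] == "RasterLayer":
        if data.ndim != 2:
            raise ValueError(f"{path}: single layer expected, got {data.ndim}D data")
        nodata = meta["nodata"]
        return RasterLayer(
            grid=grid,
            values=data,
            kind=meta["kind"],
            nodata=np.nan if nodata is None else nodata,
            categories=(
                {int(k): v for k, v in meta["categories"].items()}
                if meta.get("categories")
                else None
            ),
        )
    time_axis = [tuple(t) for t in meta["time_axis"]]
    if data.ndim != 3 or data.shape[0] != len(time_axis):
        raise ValueError(
            f"{path}: band count {data.shape[0] if data.ndim == 3 else 1} "
            f"inconsistent with {len(time_axis)} time-axis entries"
        )
    return RasterStack(grid=grid, values=data, time_axis=time_axis)


def _is_nan(x) -> bool:
    return isinstance(x, float) and np.isnan(x)


# ---------------------------------------------------------------------------
# vectors


def write_vector(layer: VectorLayer, path: str | Path) -> Path:
    """Write features as GeoJSON (coordinates in the local projected frame)."""
    path = Path(path)
    features = []
    for i, geom in enumerate(layer.geometries):
        props = {}
        if layer.attributes is not None:
            props = {
                k: (v.item() if isinstance(v, np.generic) else v)
                for k, v in layer.attributes.iloc[i].items()
            }
        features.append(
            {
                "type": "Feature",
                "geometry": json.loads(shapely.to_geojson(geom)),
                "properties": props,
            }
        )
    doc = {
        "type": "FeatureCollection",
        "ndvitrend_geometry_kind": layer.geometry_kind,
        "features": features,
    }
    path.write_text(json.dumps(doc))
    return path


def read_vector(path: str | Path) -> VectorLayer:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise IOError(f"{path} is not a GeoJSON FeatureCollection")
    geoms, rows = [], []
    for feat in doc["features"]:
        geoms.append(shapely.from_geojson(json.dumps(feat["geometry"])))
        rows.append(feat.get("properties") or {})
    kind = doc.get("ndvitrend_geometry_kind")
    if kind is None:
        kind = {
            "Point": "points",
            "MultiPoint": "points",
            "LineString": "polylines",
            "MultiLineString": "polylines",
            "Polygon": "polygons",
            "MultiPolygon": "polygons",
        }[geoms[0].geom_type]
    attrs = pd.DataFrame(rows) if any(rows) else None
    return VectorLayer(geometry_kind=kind, geometries=geoms, attributes=attrs)


# ---------------------------------------------------------------------------
# polygon series


def write_series(series: PolygonSeriesMatrix, path: str | Path) -> Path:
    """CSV dialect: rows = polygons (index ``polygon``), columns = YYYY-MM."""
    path = Path(path)
    frame = series.to_frame()
    frame.index.name = "polygon"
    frame.to_csv(path)  # default float repr round-trips exactly
    return path


def read_series(path: str | Path) -> PolygonSeriesMatrix:
    frame = pd.read_csv(path, index_col="polygon", float_precision="round_trip")
    time_axis = [(int(c[:4]), int(c[5:7])) for c in frame.columns]
    return PolygonSeriesMatrix(
        values=frame.to_numpy(dtype=float),
        polygon_ids=list(frame.index),
        time_axis=time_axis,
    )
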