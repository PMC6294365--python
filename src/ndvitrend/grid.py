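"""Core gridded/vector data containers shared by every pipeline stage.

Conventions (used consistently across the package):

* 0-based ``(row, col)`` indexing, row-major, row 0 is the *northern* edge.
* ``origin`` is the map coordinate of the upper-left pixel **corner**;
  cell centers sit at ``origin + (col + 0.5, -(row + 0.5)) * cell_size``.
* All coordinates are planar meters (synthetic scenes live in a local
  projected frame); no geodesic math anywhere.
* Continuous rasters use ``NaN`` as nodata; categorical rasters use an
  integer sentinel plus a code -> label map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely

__all__ = [
    "Grid",
    "RasterLayer",
    "RasterStack",
    "VectorLayer",
    "PolygonPartition",
    "PolygonSeriesMatrix",
]


@dataclass(frozen=True)
class Grid:
    """Geometry of a regular raster grid (pixel-corner origin, meters)."""

    n_rows: int
    n_cols: int
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinates as ``(n_rows, n_cols)`` arrays."""
        x0, y0 = self.origin
        cols = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        rows = y0 - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(cols, rows)


@dataclass
class RasterLayer:
    """One static raster: continuous values or integer category codes."""

    grid: Grid
    values: np.ndarray
    kind: str = "continuous"  # or "categorical"
    nodata: float | int = np.nan
    categories: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"layer shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown raster kind {self.kind!r}")
        if self.kind == "categorical" and self.categories is None:
            codes = np.unique(self.values[self.valid_mask()])
            self.categories = {int(c): str(int(c)) for c in codes}

    def valid_mask(self) -> np.ndarray:
        if self.kind == "continuous":
            if np.isnan(self.nodata) if isinstance(self.nodata, float) else False:
                return ~np.isnan(self.values)
            return ~np.isnan(self.values) & (self.values != self.nodata)
        return self.values != self.nodata


@dataclass
class RasterStack:
    """A monthly time series of rasters on one grid, ``values[(t, r, c)]``."""

    grid: Grid
    values: np.ndarray  # (T, n_rows, n_cols)
    time_axis: list[tuple[int, int]]  # (year, month), strictly consecutive
    nodata: float = np.nan

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1:] != self.grid.shape:
            raise ValueError(
                f"stack shape {self.values.shape} incompatible with grid "
                f"{self.grid.shape}"
            )
        self.time_axis = [(int(y), int(m)) for y, m in self.time_axis]
        if len(self.time_axis) != self.values.shape[0]:
            raise ValueError(
                f"{self.values.shape[0]} bands but {len(self.time_axis)} "
                "time-axis entries"
            )
        for (y0, m0), (y1, m1) in zip(self.time_axis, self.time_axis[1:]):
            if (y1, m1) != (y0 + m0 // 12, m0 % 12 + 1):
                raise ValueError("time axis must be strictly consecutive months")

    @property
    def n_times(self) -> int:
        return self.values.shape[0]

    def valid_mask(self) -> np.ndarray:
        """Pixels valid at every time step."""
        return ~np.isnan(self.values).any(axis=0)


@dataclass
class VectorLayer:
    """Point / polyline / polygon features in the grid's coordinate frame."""

    geometry_kind: str  # "points" | "polylines" | "polygons"
    geometries: list[shapely.Geometry]
    attributes: pd.DataFrame | None = None

    _KINDS = {
        "points": ("Point", "MultiPoint"),
        "polylines": ("LineString", "MultiLineString"),
        "polygons": ("Polygon", "MultiPolygon"),
    }

    def __post_init__(self) -> None:
        if self.geometry_kind not in self._KINDS:
            raise ValueError(f"unknown geometry kind {self.geometry_kind!r}")
        allowed = self._KINDS[self.geometry_kind]
        for g in self.geometries:
            if g.geom_type not in allowed:
                raise ValueError(
                    f"{g.geom_type} feature in a {self.geometry_kind} layer"
                )
            if not np.all(np.isfinite(shapely.get_coordinates(g))):
                raise ValueError("non-finite coordinate in vector feature")
        if self.attributes is not None and len(self.attributes) != len(
            self.geometries
        ):
            raise ValueError("attribute table length != feature count")

    def __len__(self) -> int:
        return len(self.geometries)


@dataclass
class PolygonPartition:
    """Per-pixel polygon membership; labels 1..n_polygons, 0 = nodata."""

    grid: Grid
    labels: np.ndarray
    n_polygons: int
    meta: pd.DataFrame | None = None  # one row per polygon (band, catchment, ...)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != self.grid.shape:
            raise ValueError("partition labels must match grid shape")
        present = np.unique(self.labels[self.labels > 0])
        if len(present) != self.n_polygons or (
            len(present) and (present[0] != 1 or present[-1] != self.n_polygons)
        ):
            raise ValueError("labels must be contiguous integers 1..n_polygons")

    def valid_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class PolygonSeriesMatrix:
    """Polygon-level monthly series: one row per polygon."""

    values: np.ndarray  # (n_polygons, T)
    polygon_ids: Sequence[int]
    time_axis: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.polygon_ids = [int(p) for p in self.polygon_ids]
        self.time_axis = [(int(y), int(m)) for y, m in self.time_axis]
        if self.values.shape != (len(self.polygon_ids), len(self.time_axis)):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.polygon_ids)}, {len(self.time_axis)})"
            )

    @property
    def n_polygons(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{y:04d}-{m:02d}" for y, m in self.time_axis]
        return pd.DataFrame(self.values, index=self.polygon_ids, columns=cols)
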