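"""Covariate derivations on the grid: Euclidean distance surfaces, buffer
masks, terrain slope/aspect, the mean-annual-precipitation (MAP) band by
catchment partition, and zonal statistics.

Distances use pixel-center semantics on the planar grid (meters).  Slope
and aspect use the Horn 3x3 finite-difference kernel, the de-facto GIS
standard; at grid edges the DEM is extended by linear extrapolation so an
inclined plane keeps its exact gradient everywhere.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely

from .grid import Grid, PolygonPartition, PolygonSeriesMatrix, RasterLayer, RasterStack

__all__ = [
    "euclidean_distance",
    "buffer_mask",
    "terrain_slope",
    "terrain_aspect",
    "partition_by_map",
    "zonal_mean",
    "FLAT_ASPECT",
]

#: aspect code for cells with zero slope (no defined downslope direction)
FLAT_ASPECT = -1.0


def euclidean_distance(features: VectorLayerLike, grid: Grid) -> RasterLayer:
    """Distance (m) from every cell center to the nearest feature.

    A cell whose center lies on a feature gets 0.
    """
    geoms = getattr(features, "geometries", features)
    if len(geoms) == 0:
        raise ValueError("euclidean_distance: empty feature set")
    xs, ys = grid.cell_centers()
    points = shapely.points(xs.ravel(), ys.ravel())
    merged = shapely.union_all(list(geoms))
    dist = shapely.distance(points, merged).reshape(grid.shape)
    return RasterLayer(grid=grid, values=dist, kind="continuous")


def buffer_mask(features, grid: Grid, radius: float) -> RasterLayer:
    """Binary layer: 1 where center distance to the features <= radius."""
    if radius < 0:
        raise ValueError("buffer radius must be non-negative")
    dist = euclidean_distance(features, grid)
    mask = (dist.values <= radius).astype(np.int64)
    return RasterLayer(
        grid=grid, values=mask, kind="categorical", nodata=-1,
        categories={0: "outside", 1: "inside"},
    )


def _horn_gradients(dem: RasterLayer) -> tuple[np.ndarray, np.ndarray]:
    """dz/dx (east+) and dz/dy (north+) via the Horn kernel.

    The DEM is padded by linear extrapolation (2*edge - inner) so planes
    are differentiated exactly at the borders (one-sided behaviour).
    """
    z = np.asarray(dem.values, dtype=float)
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("terrain analysis needs a DEM of at least 3x3 cells")
    zp = np.pad(z, 1, mode="reflect", reflect_type="odd")
    c = dem.grid.cell_size
    # Horn weights: corners 1, edges 2, normalized by 8*cell_size
    a = zp[:-2, :-2]; b = zp[:-2, 1:-1]; cc = zp[:-2, 2:]
    d = zp[1:-1, :-2];                    f = zp[1:-1, 2:]
    g = zp[2:, :-2];  h = zp[2:, 1:-1];  i = zp[2:, 2:]
    dzdx = ((cc + 2 * f + i) - (a + 2 * d + g)) / (8 * c)
    # rows run north -> south, so the northward derivative is row-reversed
    dzdy = ((a + 2 * b + cc) - (g + 2 * h + i)) / (8 * c)
    return dzdx, dzdy


def terrain_slope(dem: RasterLayer) -> RasterLayer:
    """Slope in degrees (>= 0) from the Horn kernel."""
    dzdx, dzdy = _horn_gradients(dem)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    slope[~dem.valid_mask()] = np.nan
    return RasterLayer(grid=dem.grid, values=slope, kind="continuous")


def terrain_aspect(dem: RasterLayer) -> RasterLayer:
    """Aspect: downslope azimuth, degrees clockwise from north in [0, 360).

    Flat cells (slope exactly 0) carry :data:`FLAT_ASPECT`.
    """
    dzdx, dzdy = _horn_gradients(dem)
    # downslope vector is -grad; azimuth measured clockwise from north
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    aspect[(dzdx == 0) & (dzdy == 0)] = FLAT_ASPECT
    aspect[~dem.valid_mask()] = np.nan
    return RasterLayer(grid=dem.grid, values=aspect, kind="continuous")


def partition_by_map(
    map_climatology: RasterLayer,
    catchments: RasterLayer,
    interval: float = 50.0,
) -> PolygonPartition:
    """Partition the landscape into MAP-band x catchment polygons.

    Band edges are half-open ``[lo + k*interval, lo + (k+1)*interval)``
    anchored at the landscape minimum rounded down to the nearest
    ``interval``.  Only nonempty (band, catchment) combinations receive a
    polygon id; ids are 1..n in (band, catchment) sort order.
    """
    if map_climatology.grid != catchments.grid:
        raise ValueError("MAP and catchment rasters must share a grid")
    mapv = np.asarray(map_climatology.values, dtype=float)
    valid = map_climatology.valid_mask() & catchments.valid_mask()
    if np.any(mapv[valid] <= 0):
        raise ValueError("MAP climatology must be strictly positive (mm/yr)")
    anchor = np.floor(mapv[valid].min() / interval) * interval
    band = np.floor((np.where(valid, mapv, anchor) - anchor) / interval).astype(int)
    catch = np.asarray(catchments.values).astype(int)

    labels = np.zeros(map_climatology.grid.shape, dtype=int)
    pairs = np.stack([band[valid], catch[valid]], axis=1)
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    labels[valid] = inverse + 1
    meta = pd.DataFrame(
        {
            "polygon": np.arange(1, len(uniq) + 1),
            "map_band_low": anchor + uniq[:, 0] * interval,
            "map_band_high": anchor + (uniq[:, 0] + 1) * interval,
            "catchment": uniq[:, 1],
        }
    )
    return PolygonPartition(
        grid=map_climatology.grid, labels=labels, n_polygons=len(uniq), meta=meta
    )


def zonal_mean(stack: RasterStack, partition: PolygonPartition) -> PolygonSeriesMatrix:
    """Polygon-mean series: entry (p, t) = mean of valid pixels of p at t."""
    if stack.grid != partition.grid:
        raise ValueError("stack and partition must share a grid")
    labels = partition.labels.ravel()
    n = partition.n_polygons
    T = stack.n_times
    out = np.full((n, T), np.nan)
    for t in range(T):
        vals = stack.values[t].ravel()
        ok = (labels > 0) & ~np.isnan(vals)
        counts = np.bincount(labels[ok], minlength=n + 1)[1:]
        sums = np.bincount(labels[ok], weights=vals[ok], minlength=n + 1)[1:]
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, t] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return PolygonSeriesMatrix(
        values=out, polygon_ids=list(range(1, n + 1)), time_axis=stack.time_axis
    )


# typing helper: anything with .geometries, or a plain list of geometries
VectorLayerLike = object
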