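"""Seeded synthetic savanna landscapes for end-to-end testing.

The generator emulates the structure of a semi-arid southern-African
study region: a decade of monthly NDVI over a gridded landscape with a
steep north-to-south mean-annual-precipitation (MAP) gradient
(1400 down to 400 mm/yr), an austral wet season (October-April),
polygon units formed by 50-mm MAP bands intersected with catchments,
monthly environmental driver stacks (precipitation, mean/max
temperature, soil moisture, PET, fire), and static social/physical
covariates (DEM, land cover, soil, population, country, inundation,
protected areas, roads, settlements, rivers).

Polygon-scale NDVI is generated from the drivers through a factor
structure (covariate regression plus random-walk common trends), and
known pixel-scale divergences are planted via static covariates:
protected areas push observed NDVI *above* the polygon signal over time
(the model would under-predict them), human footprint (road/settlement
buffers, high population) pushes it below (over-prediction), and
lowlands get a mild positive drift.  The planted per-pixel residual
slope is linear in time, so ground truth for the downstream trend test
is known exactly.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage

from .geodata import buffer_mask, euclidean_distance, partition_by_map, zonal_mean
from .grid import (
    Grid,
    PolygonPartition,
    PolygonSeriesMatrix,
    RasterLayer,
    RasterStack,
    VectorLayer,
)

__all__ = [
    "SceneConfig",
    "SceneTruth",
    "Scene",
    "make_static_landscape",
    "make_monthly_drivers",
    "make_ndvi",
    "make_scene",
    "truth_labels",
    "write_scene",
]

# monthly share of annual precipitation; wet season Oct-Apr, peak Dec-Feb,
# May-Sep (austral dry season) near zero
_PRECIP_SHARE = {
    1: 0.18, 2: 0.16, 3: 0.12, 4: 0.06, 5: 0.02, 6: 0.0,
    7: 0.0, 8: 0.0, 9: 0.04, 10: 0.10, 11: 0.14, 12: 0.18,
}
# relative fire intensity: concentrated in the late dry season
_FIRE_SHARE = {
    1: 0.05, 2: 0.05, 3: 0.05, 4: 0.1, 5: 0.2, 6: 0.4,
    7: 0.8, 8: 1.5, 9: 2.0, 10: 1.0, 11: 0.2, 12: 0.05,
}

WET_MONTHS = (10, 11, 12, 1, 2, 3, 4)
DRY_MONTHS = (5, 6, 7, 8, 9)


def _default_coefficients() -> dict[str, float]:
    # NDVI units per standard deviation of the polygon-mean driver
    return {
        "precipitation": 0.05,
        "temperature_mean": 0.01,
        "temperature_max": -0.02,
        "soil_moisture": 0.08,
        "pet": -0.03,
        "fire": -0.01,
    }


def _default_modifiers() -> dict[str, float]:
    # planted residual slopes, NDVI units per year
    return {"pa": 0.010, "human": 0.010, "lowland": 0.004}


@dataclass
class SceneConfig:
    """Knobs of the synthetic landscape; defaults are the study conditions."""

    n_rows: int = 60
    n_cols: int = 60
    cell_size: float = 250.0  # meters, MODIS-like
    n_years: int = 10
    start_year: int = 2001
    seed: int = 0
    map_range: tuple[float, float] = (400.0, 1400.0)  # mm/yr, south -> north
    map_band_interval: float = 50.0
    n_catchments: int = 3
    n_trends: int = 2
    driver_coefficients: dict[str, float] = field(default_factory=_default_coefficients)
    modifier_effects: dict[str, float] = field(default_factory=_default_modifiers)
    trend_loading_sd: float = 0.008
    noise_sd: float = 0.05
    soil_memory: float = 0.6  # AR(1) coefficient of soil moisture
    annual_precip_cv: float = 0.25  # lognormal sd of yearly multipliers
    min_effect: float = 0.004  # NDVI/yr below which a plant counts as "none"

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise ValueError("need at least 2 years of monthly data")
        if not self.map_range[0] < self.map_range[1]:
            raise ValueError("map_range must be (min, max) with min < max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_rows < 12 or self.n_cols < 12:
            raise ValueError("grid too small to host the synthetic features")

    @property
    def grid(self) -> Grid:
        return Grid(self.n_rows, self.n_cols, self.cell_size, origin=(0.0, 0.0))

    @property
    def time_axis(self) -> list[tuple[int, int]]:
        return [
            (self.start_year + t // 12, t % 12 + 1)
            for t in range(12 * self.n_years)
        ]

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SceneTruth:
    """Everything the generator knows that the pipeline must recover."""

    driver_coefficients: dict[str, float]
    modifier_slope: RasterLayer  # m_p, NDVI/yr per pixel
    class_raster: RasterLayer  # -1 over / 0 none / +1 under at min_effect
    states: np.ndarray  # (n_trends, T) common-trend paths
    loadings: np.ndarray  # (n_polygons, n_trends)
    intercepts: np.ndarray  # (n_polygons,)
    polygon_signal: PolygonSeriesMatrix  # noise-free s_p(t)


@dataclass
class Scene:
    config: SceneConfig
    ndvi: RasterStack
    drivers: dict[str, RasterStack]
    statics: dict[str, RasterLayer]
    vectors: dict[str, VectorLayer]
    partition: PolygonPartition
    truth: SceneTruth


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    """Independent streams so e.g. changing noise does not move geometry."""
    names = ["landscape", "drivers", "states", "noise"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _smooth_field(rng, shape, sigma) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="nearest")
    return f / max(f.std(), 1e-12)


# ---------------------------------------------------------------------------
# statics + vectors + partition


def make_static_landscape(
    config: SceneConfig,
) -> tuple[dict[str, RasterLayer], dict[str, VectorLayer], PolygonPartition]:
    """Build DEM, MAP climatology, categorical layers, vectors and the
    MAP-band x catchment partition. Deterministic given ``config.seed``."""
    rng = _rngs(config.seed)["landscape"]
    grid = config.grid
    nr, nc = grid.shape
    north = (nr - 1 - np.arange(nr))[:, None] / (nr - 1)  # 1 at row 0 (north)
    north = np.broadcast_to(north, (nr, nc))

    dem = 950.0 + 350.0 * north + 40.0 * _smooth_field(rng, (nr, nc), 6)
    lo, hi = config.map_range
    map_clim = lo + (hi - lo) * north + 20.0 * _smooth_field(rng, (nr, nc), 5)
    map_clim = np.clip(map_clim, lo + 0.5, hi - 0.5)

    # catchments: vertical strips with wavy boundaries
    wiggles = [
        np.round(2.5 * _smooth_field(rng, (nr,), 4)).astype(int)
        for _ in range(config.n_catchments - 1)
    ]
    catch = np.zeros((nr, nc), dtype=int)
    for k, w in enumerate(wiggles, start=1):
        bound = np.clip(np.round((k * nc) / config.n_catchments).astype(int) + w, 1, nc - 1)
        catch += np.arange(nc)[None, :] >= bound[:, None]
    catch += 1

    land_cover = np.digitize(
        _smooth_field(rng, (nr, nc), 4) + 0.8 * north, [-0.8, 0.0, 0.8]
    ) + 1
    soil = np.digitize(_smooth_field(rng, (nr, nc), 7), [-0.4, 0.6]) + 1
    country = (np.arange(nr)[:, None] + 3 * _smooth_field(rng, (nr, nc), 8)
               > 0.55 * nr).astype(int) + 1
    country = np.broadcast_to(country, (nr, nc)).copy()
    inundated = ((dem < np.quantile(dem, 0.08))
                 & (_smooth_field(rng, (nr, nc), 5) > -0.5)).astype(int)

    cs = grid.cell_size
    width, height = nc * cs, nr * cs

    def xy(fx: float, fy: float) -> tuple[float, float]:
        # fractional (x east, y from north edge downward) -> map coords
        return (fx * width, -fy * height)

    pa_poly = shapely.box(*xy(0.12, 0.80), *xy(0.42, 0.55))
    protected = VectorLayer("polygons", [pa_poly],
                            pd.DataFrame({"name": ["synthetic reserve"]}))

    def wavy_line(points: list[tuple[float, float]], jitter: float) -> shapely.LineString:
        pts = [
            (x + jitter * rng.normal() * cs, y + jitter * rng.normal() * cs)
            for x, y in points
        ]
        return shapely.LineString(pts)

    road_ew = wavy_line([xy(0.0, 0.30), xy(0.35, 0.32), xy(0.7, 0.28), xy(1.0, 0.30)], 1.0)
    road_ns = wavy_line([xy(0.62, 0.0), xy(0.60, 0.4), xy(0.65, 0.7), xy(0.63, 1.0)], 1.0)
    roads = VectorLayer("polylines", [road_ew, road_ns],
                        pd.DataFrame({"surface": ["tar", "unpaved"]}))

    river = wavy_line([xy(0.85, 0.0), xy(0.82, 0.3), xy(0.88, 0.6), xy(0.80, 1.0)], 1.5)
    rivers = VectorLayer("polylines", [river], pd.DataFrame({"name": ["river"]}))

    settle_fracs = [(0.2, 0.30), (0.62, 0.31), (0.63, 0.75), (0.85, 0.12)]
    settle_pts = [
        shapely.Point(x + rng.normal() * cs, y + rng.normal() * cs)
        for x, y in (xy(fx, fy) for fx, fy in settle_fracs)
    ]
    settlements = VectorLayer(
        "points", settle_pts,
        pd.DataFrame({"name": [f"settlement_{i}" for i in range(len(settle_pts))]}),
    )

    # population clusters around settlements, with a noisy rural floor
    dist_settle = euclidean_distance(settlements, grid).values
    population = (
        60.0 * np.exp(-dist_settle / (8 * cs))
        + np.exp(0.5 * _smooth_field(rng, (nr, nc), 3))
    )

    statics = {
        "dem": RasterLayer(grid, dem),
        "map_climatology": RasterLayer(grid, map_clim),
        "catchments": RasterLayer(grid, catch, kind="categorical", nodata=0),
        "land_cover": RasterLayer(
            grid, land_cover, kind="categorical", nodata=0,
            categories={1: "grassland", 2: "shrubland", 3: "woodland", 4: "forest"},
        ),
        "soil": RasterLayer(
            grid, soil, kind="categorical", nodata=0,
            categories={1: "arenosol", 2: "luvisol", 3: "vertisol"},
        ),
        "country": RasterLayer(
            grid, country, kind="categorical", nodata=0,
            categories={1: "north_country", 2: "south_country"},
        ),
        "inundated": RasterLayer(
            grid, inundated, kind="categorical", nodata=-1,
            categories={0: "dry", 1: "inundated"},
        ),
        "population": RasterLayer(grid, population),
    }
    vectors = {
        "protected_areas": protected,
        "roads": roads,
        "settlements": settlements,
        "rivers": rivers,
    }
    partition = partition_by_map(
        statics["map_climatology"], statics["catchments"], config.map_band_interval
    )
    return statics, vectors, partition


# ---------------------------------------------------------------------------
# monthly drivers


def make_monthly_drivers(
    config: SceneConfig, statics: dict[str, RasterLayer]
) -> dict[str, RasterStack]:
    """Monthly environmental stacks with realistic seasonal structure."""
    rng = _rngs(config.seed)["drivers"]
    grid = config.grid
    time_axis = config.time_axis
    T = len(time_axis)
    nr, nc = grid.shape
    mapv = statics["map_climatology"].values
    dem = statics["dem"].values

    year_mult = np.exp(
        rng.normal(0.0, config.annual_precip_cv, size=config.n_years)
        - config.annual_precip_cv**2 / 2
    )

    precip = np.empty((T, nr, nc))
    for t, (y, m) in enumerate(time_axis):
        share = _PRECIP_SHARE[m]
        pix_mult = np.exp(rng.normal(0.0, 0.2, size=(nr, nc)) - 0.02)
        wet = share * mapv * year_mult[y - config.start_year] * pix_mult
        if m in DRY_MONTHS and share > 0:
            wet *= rng.random((nr, nc)) < 0.5  # zero-inflated shoulder months
        precip[t] = wet

    month_phase = np.array([2 * np.pi * (m - 10) / 12 for _, m in time_axis])
    elev_adj = -6.5 * (dem - 1000.0) / 1000.0
    t_mean = (
        24.0 + elev_adj
        + 5.0 * np.cos(month_phase)[:, None, None]
        + rng.normal(0, 0.5, size=(T, nr, nc))
    )
    t_max = t_mean + 8.0 + rng.normal(0, 0.5, size=(T, nr, nc))

    soil_m = np.empty_like(precip)
    rho = config.soil_memory
    soil_m[0] = precip[:12].mean(axis=0)
    for t in range(1, T):
        soil_m[t] = rho * soil_m[t - 1] + (1 - rho) * precip[t]

    sm_scale = max(soil_m.mean(), 1e-9)
    pet = np.clip(
        150.0
        - 60.0 * soil_m / sm_scale
        + 15.0 * np.cos(month_phase)[:, None, None]
        + rng.normal(0, 3.0, size=(T, nr, nc)),
        10.0,
        None,
    )

    fire = np.empty_like(precip)
    dryness = 1.0 + (mapv.max() - mapv) / (mapv.max() - mapv.min() + 1e-9)
    for t, (_, m) in enumerate(time_axis):
        fire[t] = rng.poisson(0.4 * _FIRE_SHARE[m] * dryness)

    mk = lambda a: RasterStack(grid=grid, values=a, time_axis=time_axis)
    return {
        "precipitation": mk(precip),
        "temperature_mean": mk(t_mean),
        "temperature_max": mk(t_max),
        "soil_moisture": mk(soil_m),
        "pet": mk(pet),
        "fire": mk(fire),
    }


# ---------------------------------------------------------------------------
# NDVI + truth


def _standardize_rows(a: np.ndarray) -> np.ndarray:
    mu = a.mean(axis=1, keepdims=True)
    sd = a.std(axis=1, keepdims=True)
    return np.where(sd > 0, (a - mu) / np.where(sd > 0, sd, 1.0), 0.0)


def planted_slopes(
    config: SceneConfig,
    statics: dict[str, RasterLayer],
    vectors: dict[str, VectorLayer],
) -> np.ndarray:
    """Assemble the per-pixel planted residual slope m_p (NDVI/yr)."""
    grid = config.grid
    xs, ys = grid.cell_centers()
    pts = shapely.points(xs.ravel(), ys.ravel())
    eff = config.modifier_effects
    m = np.zeros(grid.shape)

    pa_geom = shapely.union_all(vectors["protected_areas"].geometries)
    in_pa = shapely.covers(pa_geom, pts).reshape(grid.shape)
    m += eff.get("pa", 0.0) * in_pa

    road_buf = buffer_mask(vectors["roads"], grid, 90.0).values == 1
    settle_buf = buffer_mask(vectors["settlements"], grid, 1000.0).values == 1
    pop = statics["population"].values
    high_pop = pop > np.quantile(pop, 0.90)
    m -= eff.get("human", 0.0) * (road_buf | settle_buf | high_pop)

    dem = statics["dem"].values
    lowland = dem < np.quantile(dem, 0.10)
    m += eff.get("lowland", 0.0) * lowland
    return m


def make_ndvi(
    config: SceneConfig,
    statics: dict[str, RasterLayer],
    vectors: dict[str, VectorLayer],
    drivers: dict[str, RasterStack],
    partition: PolygonPartition,
) -> tuple[RasterStack, SceneTruth]:
    """Generate the NDVI stack and its ground truth.

    Polygon signal: s_p(t) = mu_p + sum_k c_k z_pk(t) + (Gamma alpha_t)_p
    with z the standardized polygon-mean drivers and alpha random-walk
    common trends.  Pixel NDVI: s + m_pixel * t/12 + Gaussian noise,
    clamped to [-1, 1].
    """
    rng = _rngs(config.seed)
    grid = config.grid
    time_axis = config.time_axis
    T = len(time_axis)
    N = partition.n_polygons
    M = config.n_trends

    poly_map = zonal_mean(
        RasterStack(grid=grid, values=np.broadcast_to(
            statics["map_climatology"].values, (1,) + grid.shape).copy(),
            time_axis=[time_axis[0]]),
        partition,
    ).values[:, 0]
    lo, hi = config.map_range
    intercepts = 0.20 + 0.35 * (poly_map - lo) / (hi - lo)

    signal = np.tile(intercepts[:, None], (1, T))
    for name, coef in config.driver_coefficients.items():
        if coef == 0.0 or name not in drivers:
            continue
        z = _standardize_rows(zonal_mean(drivers[name], partition).values)
        signal = signal + coef * z

    states = np.cumsum(rng["states"].standard_normal((M, T)), axis=1) if M else np.zeros((0, T))
    loadings = (
        rng["states"].normal(0.0, config.trend_loading_sd, size=(N, M))
        if M
        else np.zeros((N, 0))
    )
    signal = signal + loadings @ states

    m_pix = planted_slopes(config, statics, vectors)
    years = np.arange(T) / 12.0

    ndvi = signal[partition.labels - 1, :]  # (nr, nc, T); label 0 fixed below
    ndvi = np.moveaxis(ndvi, -1, 0)
    ndvi = ndvi + m_pix[None, :, :] * years[:, None, None]
    if config.noise_sd > 0:
        ndvi = ndvi + rng["noise"].normal(0.0, config.noise_sd, size=ndvi.shape)
    clipped = (ndvi < -1) | (ndvi > 1)
    if clipped.mean() > 0.05:
        warnings.warn(
            f"{100 * clipped.mean():.1f}% of NDVI values clamped to [-1, 1]; "
            "signal too large for the NDVI scale"
        )
    ndvi = np.clip(ndvi, -1.0, 1.0)
    ndvi[:, partition.labels == 0] = np.nan

    truth = SceneTruth(
        driver_coefficients=dict(config.driver_coefficients),
        modifier_slope=RasterLayer(grid, m_pix),
        class_raster=_label_layer(grid, m_pix, config.min_effect),
        states=states,
        loadings=loadings,
        intercepts=intercepts,
        polygon_signal=PolygonSeriesMatrix(
            values=signal, polygon_ids=list(range(1, N + 1)), time_axis=time_axis
        ),
    )
    stack = RasterStack(grid=grid, values=ndvi, time_axis=time_axis)
    return stack, truth


def _label_layer(grid: Grid, m: np.ndarray, min_effect: float) -> RasterLayer:
    cls = np.zeros(grid.shape, dtype=int)
    cls[m >= min_effect] = 1
    cls[m <= -min_effect] = -1
    return RasterLayer(
        grid, cls, kind="categorical", nodata=-99,
        categories={-1: "over_predicted", 0: "none", 1: "under_predicted"},
    )


def truth_labels(truth: SceneTruth, min_effect: float) -> RasterLayer:
    """Re-threshold the planted slopes at a chosen minimum effect."""
    return _label_layer(
        truth.modifier_slope.grid, truth.modifier_slope.values, min_effect
    )


#: minimum *within-polygon* residual slope (NDVI/yr) the trend stage is
#: expected to detect with >= 90% sensitivity at the default noise level;
#: fixed by the pilot simulation in scripts/pilot_sensitivity.py
MIN_DETECTABLE_EFFECT = 0.005


def effective_slopes(truth: SceneTruth, partition: PolygonPartition) -> np.ndarray:
    """Planted slope minus its polygon mean: the component of the plant
    the residual-trend stage can see.

    The polygon-mean component of a planted divergence shifts the
    polygon's own NDVI series and is therefore absorbed into the
    polygon-level prediction; only the within-polygon deviation survives
    in the residuals.
    """
    m = truth.modifier_slope.values
    labels = partition.labels
    out = np.full(m.shape, np.nan)
    for p in range(1, partition.n_polygons + 1):
        sel = labels == p
        out[sel] = m[sel] - m[sel].mean()
    return out


def make_scene(config: SceneConfig | None = None, **kwargs) -> Scene:
    """Generate a full scene (statics, drivers, NDVI, partition, truth)."""
    if config is None:
        config = SceneConfig(**kwargs)
    statics, vectors, partition = make_static_landscape(config)
    drivers = make_monthly_drivers(config, statics)
    ndvi, truth = make_ndvi(config, statics, vectors, drivers, partition)
    return Scene(
        config=config,
        ndvi=ndvi,
        drivers=drivers,
        statics=statics,
        vectors=vectors,
        partition=partition,
        truth=truth,
    )


def write_scene(scene: Scene, outdir: str | Path) -> Path:
    """Write the scene (TIFF/GeoJSON/CSV) plus a manifest with the seed
    and config hash."""
    from . import io as nio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": scene.config.seed,
        "config_hash": scene.config.config_hash(),
        "config": asdict(scene.config),
        "artifacts": [],
    }

    def record(path: Path) -> None:
        manifest["artifacts"].append(path.name)

    record(nio.write_raster(scene.ndvi, outdir / "ndvi.tif"))
    for name, stack in scene.drivers.items():
        record(nio.write_raster(stack, outdir / f"driver_{name}.tif"))
    for name, layer in scene.statics.items():
        record(nio.write_raster(layer, outdir / f"static_{name}.tif"))
    for name, vec in scene.vectors.items():
        record(nio.write_vector(vec, outdir / f"{name}.geojson"))
    record(
        nio.write_raster(
            RasterLayer(scene.partition.grid, scene.partition.labels,
                        kind="categorical", nodata=0),
            outdir / "partition.tif",
        )
    )

    m = scene.truth.modifier_slope.values
    cls = scene.truth.class_raster.values
    valid = scene.partition.labels > 0
    rows, cols = np.nonzero(valid)
    pd.DataFrame(
        {
            "row": rows,
            "col": cols,
            "modifier_slope": m[rows, cols],
            "true_class": cls[rows, cols],
        }
    ).to_csv(outdir / "truth.csv", index=False)
    record(outdir / "truth.csv")
    record(nio.write_series(scene.truth.polygon_signal, outdir / "polygon_signal.csv"))

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir
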