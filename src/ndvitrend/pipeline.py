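"""Five-stage pipeline: simulate -> dfa -> trend -> attribute -> report.

Each stage reads the previous stage's on-disk artifacts and writes its
own under the output directory, embedding the seed and config hash so
any report can be re-derived.  Stages are idempotent given identical
config + seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .attribution import (
    FEATURE_ORDER,
    SamplePlan,
    TrendDriverForest,
    class_histograms,
    combined_explained,
    extract_features,
    sample_points,
)
from .dfa import DynamicFactorAnalysis
from .geodata import (
    buffer_mask,
    euclidean_distance,
    terrain_aspect,
    terrain_slope,
    zonal_mean,
)
from .grid import PolygonPartition, RasterLayer, RasterStack
from .scene import SceneConfig, make_scene, write_scene
from .trend import ResidualTrendAnalysis, difference

log = logging.getLogger("ndvitrend")

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "load_config",
    "cmd_simulate",
    "cmd_dfa",
    "cmd_trend",
    "cmd_attribute",
    "cmd_report",
    "run_all",
]


class ConfigError(ValueError):
    """Invalid pipeline configuration (reports the offending field)."""


@dataclass
class DfaSettings:
    m_trends: int = 2
    tol: float = 1e-6
    max_iter: int = 2000


@dataclass
class TrendSettings:
    alpha: float = 0.1
    extreme: str | float = "group_median"


@dataclass
class RfSettings:
    n_trees: int = 500
    mtry: int | None = None
    n_points: int = 150
    spacing: float = 1.5


@dataclass
class PipelineConfig:
    outdir: str = "ndvitrend_run"
    seed: int = 0
    scene: SceneConfig = field(default_factory=SceneConfig)
    dfa: DfaSettings = field(default_factory=DfaSettings)
    trend: TrendSettings = field(default_factory=TrendSettings)
    rf: RfSettings = field(default_factory=RfSettings)

    def __post_init__(self) -> None:
        if not 0 < self.trend.alpha < 1:
            raise ConfigError(f"trend.alpha={self.trend.alpha} outside (0, 1)")
        # one seed drives everything unless sub-seeds are set explicitly
        self.scene.seed = self.scene.seed or self.seed

    def config_hash(self) -> str:
        import hashlib

        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _build(cls, data: dict, path: str):
    names = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, val in data.items():
        if key not in names:
            raise ConfigError(f"unknown config field {path}{key}")
        ftype = names[key].type
        if isinstance(val, dict) and key in ("scene", "dfa", "trend", "rf"):
            sub = {"scene": SceneConfig, "dfa": DfaSettings,
                   "trend": TrendSettings, "rf": RfSettings}[key]
            val = _build(sub, val, f"{path}{key}.")
        if key in ("map_range", "modifier_effects", "driver_coefficients") and isinstance(val, list):
            val = tuple(val)
        kwargs[key] = val
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config at {path or 'top level'}: {exc}") from exc


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
    data.update(overrides)
    return _build(PipelineConfig, data, "")


# ---------------------------------------------------------------------------


def _outdir(cfg: PipelineConfig) -> Path:
    p = Path(cfg.outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the '{stage}' stage first"
        )
    return path


def cmd_simulate(cfg: PipelineConfig) -> Path:
    """Generate the synthetic scene and write it to <outdir>/scene."""
    scene = make_scene(cfg.scene)
    out = write_scene(scene, _outdir(cfg) / "scene")
    log.info("scene written to %s (%d polygons)", out, scene.partition.n_polygons)
    return out


def _load_scene_dir(cfg: PipelineConfig):
    sdir = _require(_outdir(cfg) / "scene", "simulate")
    ndvi = nio.read_raster(sdir / "ndvi.tif")
    part_layer = nio.read_raster(sdir / "partition.tif")
    labels = np.asarray(part_layer.values, dtype=int)
    partition = PolygonPartition(
        grid=part_layer.grid, labels=labels, n_polygons=int(labels.max())
    )
    return sdir, ndvi, partition


def cmd_dfa(cfg: PipelineConfig) -> DynamicFactorAnalysis:
    """Fit the dynamic factor model to polygon-mean NDVI with
    landscape-mean standardized environmental covariate series."""
    sdir, ndvi, partition = _load_scene_dir(cfg)
    y = zonal_mean(ndvi, partition)
    driver_files = sorted(sdir.glob("driver_*.tif"))
    names = [f.stem.replace("driver_", "") for f in driver_files]
    series = []
    for f in driver_files:
        stack = nio.read_raster(f)
        s = np.nanmean(stack.values.reshape(stack.n_times, -1), axis=1)
        sd = s.std()
        series.append((s - s.mean()) / (sd if sd > 0 else 1.0))
    x = np.vstack(series) if series else None

    model = DynamicFactorAnalysis(
        n_trends=cfg.dfa.m_trends, tol=cfg.dfa.tol, max_iter=cfg.dfa.max_iter
    ).fit(y, x)
    pred = model.predict()

    ddir = _outdir(cfg) / "dfa"
    ddir.mkdir(exist_ok=True)
    nio.write_series(pred, ddir / "ndvi_pred.csv")
    report = model.summary()
    report["covariates"] = names
    report["config_hash"] = cfg.config_hash()
    report["seed"] = cfg.seed
    (ddir / "model.json").write_text(json.dumps(report, indent=2))
    log.info("DFA: loglik=%.2f AIC=%.2f iters=%d", model.loglik_, model.aic_,
             model.n_iter_)
    return model


def cmd_trend(cfg: PipelineConfig) -> ResidualTrendAnalysis:
    """Difference obs from predictions and classify residual trends."""
    _, ndvi, partition = _load_scene_dir(cfg)
    pred = nio.read_series(_require(_outdir(cfg) / "dfa" / "ndvi_pred.csv", "dfa"))
    resid = difference(ndvi, pred, partition)
    rta = ResidualTrendAnalysis(
        alpha=cfg.trend.alpha, extreme=cfg.trend.extreme
    ).fit(resid)

    tdir = _outdir(cfg) / "trend"
    tdir.mkdir(exist_ok=True)
    nio.write_raster(rta.class_layer(), tdir / "classes.tif")
    for name in ("tau", "p", "beta"):
        nio.write_raster(
            RasterLayer(rta.grid_, getattr(rta, f"{name}_")), tdir / f"{name}.tif"
        )
    summary = rta.summary_.copy()
    summary.to_csv(tdir / "summary.csv", header=["percent"])
    log.info("trend classes: %s", summary.to_dict())
    return rta


def derive_covariate_layers(
    statics: dict[str, RasterLayer], vectors: dict
) -> dict[str, RasterLayer]:
    """Assemble the attribution covariate roster from statics + vectors."""
    grid = statics["dem"].grid
    return {
        "elevation": statics["dem"],
        "slope": terrain_slope(statics["dem"]),
        "aspect": terrain_aspect(statics["dem"]),
        "land_cover": statics["land_cover"],
        "soil": statics["soil"],
        "country": statics["country"],
        "population": statics["population"],
        "protected_area": buffer_mask(vectors["protected_areas"], grid, 0.0),
        "inundated": statics["inundated"],
        "dist_road": euclidean_distance(vectors["roads"], grid),
        "dist_settlement": euclidean_distance(vectors["settlements"], grid),
        "dist_river": euclidean_distance(vectors["rivers"], grid),
        "within_90m_road": buffer_mask(vectors["roads"], grid, 90.0),
        "within_90m_river": buffer_mask(vectors["rivers"], grid, 90.0),
        "within_1km_settlement": buffer_mask(vectors["settlements"], grid, 1000.0),
    }


def cmd_attribute(cfg: PipelineConfig) -> TrendDriverForest:
    """Sample the significant surfaces, extract covariates, fit the forest."""
    sdir = _require(_outdir(cfg) / "scene", "simulate")
    classes = nio.read_raster(_require(_outdir(cfg) / "trend" / "classes.tif", "trend"))
    cls = np.asarray(classes.values, dtype=float)
    cls[cls == -99] = np.nan

    statics = {
        f.stem.replace("static_", ""): nio.read_raster(f)
        for f in sorted(sdir.glob("static_*.tif"))
    }
    vectors = {
        f.stem: nio.read_vector(f) for f in sorted(sdir.glob("*.geojson"))
    }
    layers = derive_covariate_layers(statics, vectors)

    sign = np.where(np.isnan(cls), 0, np.sign(cls)).astype(int)
    plan = SamplePlan(n_points=cfg.rf.n_points, spacing=cfg.rf.spacing,
                      seed=cfg.seed)
    points = sample_points(sign, classes=(1, -1), plan=plan)
    table = extract_features(points, layers)
    # keep the four-way class for the histogram view
    table["class4"] = cls[table["row"], table["col"]].astype(int)

    forest = TrendDriverForest(
        n_trees=cfg.rf.n_trees, mtry=cfg.rf.mtry, random_state=cfg.seed
    ).fit(table.drop(columns=["class4"]))

    adir = _outdir(cfg) / "rf"
    adir.mkdir(exist_ok=True)
    table.to_csv(adir / "features.csv", index=False)
    codemaps = {
        name: {str(k): v for k, v in layers[name].categories.items()}
        for name in FEATURE_ORDER
        if layers[name].kind == "categorical" and layers[name].categories
    }
    (adir / "features_codemaps.json").write_text(json.dumps(codemaps, indent=2))

    imp = pd.DataFrame(
        {
            "mda": forest.importance_mda(seed=cfg.seed),
            "mda_normalized": forest.importance_mda(seed=cfg.seed, normalize=True),
            "gini": forest.importance_gini(),
            "gini_normalized": forest.importance_gini(normalize=True),
            "mda_under": forest.importance_mda(seed=cfg.seed, restrict_class=1),
            "mda_over": forest.importance_mda(seed=cfg.seed, restrict_class=-1),
        }
    )
    imp.index.name = "covariate"
    imp.to_csv(adir / "importances.csv")

    hist_table = table.drop(columns=["label"]).rename(columns={"class4": "label"})
    class_histograms(hist_table).to_csv(adir / "histograms.csv", index=False)

    summary = forest.summary()
    summary["config_hash"] = cfg.config_hash()
    summary["seed"] = cfg.seed
    summary["n_rejected_points"] = int(table.attrs.get("n_rejected", 0))
    (adir / "model.json").write_text(json.dumps(summary, indent=2))
    log.info("RF OOB accuracy: %.3f", forest.oob_accuracy_)
    return forest


def cmd_report(cfg: PipelineConfig) -> dict:
    """Final accounting mirroring the two-stage explained fraction."""
    out = _outdir(cfg)
    summary = pd.read_csv(
        _require(out / "trend" / "summary.csv", "trend"), index_col=0
    )["percent"]
    rf = json.loads(_require(out / "rf" / "model.json", "attribute").read_text())
    imp = pd.read_csv(out / "rf" / "importances.csv", index_col="covariate")

    correct = float(summary["correct_pct"])
    oob_acc_pct = round(100.0 * rf["oob_accuracy"], 2)
    report = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "landscape_pct": {
            "correct": correct,
            "under_predicted": float(summary["under_total"]),
            "over_predicted": float(summary["over_total"]),
            "changed_sum": float(summary["changed_sum"]),
            "changed_complement": float(summary["changed_complement"]),
        },
        "rf_oob_accuracy_pct": oob_acc_pct,
        "combined_explained_pct": combined_explained(correct, oob_acc_pct),
        "importance_ranking_mda": list(
            imp["mda"].sort_values(ascending=False).index
        ),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))

    lines = [
        "ndvitrend pipeline report",
        f"config hash : {report['config_hash']}  seed: {cfg.seed}",
        "",
        f"correctly predicted landscape : {correct:.2f}%",
        f"under-predicted               : {summary['under_total']:.2f}%",
        f"over-predicted                : {summary['over_total']:.2f}%",
        f"(under+over sum {summary['changed_sum']:.2f}%,"
        f" complement of correct {summary['changed_complement']:.2f}%)",
        f"RF OOB accuracy               : {oob_acc_pct:.2f}%",
        f"combined explained            : {report['combined_explained_pct']:.2f}%",
        "",
        "top covariates by mean decrease in accuracy:",
        *(f"  {i + 1}. {name}" for i, name in
          enumerate(report["importance_ranking_mda"][:5])),
    ]
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return report


def run_all(cfg: PipelineConfig) -> dict:
    cmd_simulate(cfg)
    cmd_dfa(cfg)
    cmd_trend(cfg)
    cmd_attribute(cfg)
    return cmd_report(cfg)
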