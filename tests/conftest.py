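import warnings

import numpy as np
import pytest

from ndvitrend.grid import Grid
from ndvitrend.scene import SceneConfig, make_scene


@pytest.fixture(scope="session")
def default_scene():
    """The standard 60x60, 10-year synthetic landscape (seed 7)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_scene(SceneConfig(seed=7))


@pytest.fixture(scope="session")
def small_scene():
    """A quick 24x24 scene for plumbing tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_scene(SceneConfig(n_rows=24, n_cols=24, seed=3))


@pytest.fixture()
def grid10():
    return Grid(10, 10, 30.0)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One small end-to-end pipeline run shared by the orchestration tests."""
    from ndvitrend.pipeline import PipelineConfig, run_all

    out = tmp_path_factory.mktemp("pipe") / "run"
    cfg = PipelineConfig(outdir=str(out), seed=11)
    cfg.scene.n_rows = cfg.scene.n_cols = 36
    cfg.dfa.max_iter = 200
    cfg.rf.n_trees = 150
    cfg.rf.n_points = 60
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = run_all(cfg)
    return cfg, report


def rng(seed=0):
    return np.random.default_rng(seed)
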