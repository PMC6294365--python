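"""Point sampling, feature extraction, forest bookkeeping, importances."""

import numpy as np
import pandas as pd
import pytest

from ndvitrend.attribution import (
    SamplePlan,
    TrendDriverForest,
    class_histograms,
    combined_explained,
    extract_features,
    majority_vote,
    sample_points,
)
from ndvitrend.grid import Grid, RasterLayer


def separable_table(n=1000, seed=0, extra_noise_features=3):
    """Two classes perfectly separated by the first feature."""
    rng = np.random.default_rng(seed)
    y = np.repeat([1, -1], n // 2)
    driver = np.where(y > 0, rng.uniform(1, 2, n), rng.uniform(-2, -1, n))
    data = {"driver": driver}
    for i in range(extra_noise_features):
        data[f"noise_{i}"] = rng.normal(size=n)
    table = pd.DataFrame(data)
    table["label"] = y
    return table


class TestSamplePoints:
    def _raster(self):
        cls = np.zeros((20, 20), dtype=int)
        cls[:10] = 1
        cls[15:] = -1
        return cls

    def test_exhaustive_case(self):
        cls = self._raster()
        plan = SamplePlan(n_points=200, spacing=0, seed=1)
        pts = sample_points(cls, classes=[1], plan=plan)
        assert len(pts) == 200
        got = set(zip(pts["row"], pts["col"]))
        want = set(zip(*np.nonzero(cls == 1)))
        assert got == want

    def test_determinism_and_class_purity(self):
        cls = self._raster()
        plan = SamplePlan(n_points=15, spacing=2.0, seed=5)
        a = sample_points(cls, classes=[1, -1], plan=plan)
        b = sample_points(cls, classes=[1, -1], plan=plan)
        pd.testing.assert_frame_equal(a, b)
        assert np.all(cls[a["row"], a["col"]] == a["label"])

    def test_spacing_enforced(self):
        cls = self._raster()
        plan = SamplePlan(n_points=10, spacing=3.0, seed=2)
        pts = sample_points(cls, classes=[1], plan=plan)
        xy = pts[["row", "col"]].to_numpy().astype(float)
        d2 = ((xy[:, None] - xy[None]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        assert d2.min() >= 9.0

    def test_shortfall_error_names_class(self):
        cls = self._raster()
        with pytest.raises(ValueError, match="class -1"):
            sample_points(cls, classes=[-1],
                          plan=SamplePlan(n_points=500, spacing=0, seed=0))

    def test_absent_class_error(self):
        with pytest.raises(ValueError, match="not present"):
            sample_points(np.zeros((5, 5), dtype=int), classes=[7],
                          plan=SamplePlan(n_points=1, spacing=0, seed=0))


class TestExtract:
    def test_values_match_layers_and_nodata_rejected(self):
        g = Grid(8, 8, 30.0)
        elev = np.arange(64, dtype=float).reshape(8, 8)
        elev[0, 0] = np.nan
        layers = {"elevation": RasterLayer(g, elev),
                  "protected_area": RasterLayer(
                      g, np.eye(8, dtype=int), kind="categorical", nodata=-1)}
        pts = pd.DataFrame({"row": [0, 1, 2], "col": [0, 1, 5], "label": [1, 1, -1]})
        with pytest.warns(UserWarning, match="rejected 1"):
            table = extract_features(pts, layers,
                                     feature_order=["elevation", "protected_area"])
        assert len(table) == 2
        assert table.attrs["n_rejected"] == 1
        assert table["elevation"].tolist() == [9.0, 21.0]
        assert table["protected_area"].tolist() == [1, 0]

    def test_missing_layer_error(self):
        pts = pd.DataFrame({"row": [0], "col": [0], "label": [1]})
        with pytest.raises(KeyError, match="slope"):
            extract_features(pts, {}, feature_order=["slope"])


def test_majority_vote_worked_example():
    """500 trees: 400 votes for class 'woodland' (2), 100 for
    'grassland' (1) -> woodland wins; exact ties go to the smaller code."""
    classes = np.array([1, 2])  # 1 grassland, 2 woodland
    votes = np.array([[100, 400], [250, 250], [500, 0]])
    assert majority_vote(votes, classes).tolist() == [2, 1, 1]


class TestForest:
    def test_separable_oob_near_zero(self):
        table = separable_table()
        f = TrendDriverForest(n_trees=100, random_state=0).fit(table)
        assert f.oob_error_ <= 0.01
        assert f.predict(table.drop(columns="label")).tolist() == \
            table["label"].tolist()

    def test_permuted_labels_oob_near_chance(self):
        table = separable_table(n=600, seed=1)
        rng = np.random.default_rng(2)
        y = table["label"].to_numpy().copy()
        rng.shuffle(y)
        f = TrendDriverForest(n_trees=100, random_state=0).fit(
            table.drop(columns="label"), y
        )
        max_prior = max(np.mean(y == 1), np.mean(y == -1))
        assert f.oob_error_ == pytest.approx(1 - max_prior, abs=0.07)

    def test_bootstrap_bookkeeping(self):
        table = separable_table(n=2000, seed=3)
        f = TrendDriverForest(n_trees=60, random_state=1).fit(table)
        n = len(table)
        assert f.bootstrap_indices_.shape == (60, n)
        uniq = np.array([len(np.unique(idx)) / n for idx in f.bootstrap_indices_])
        assert uniq.mean() == pytest.approx(1 - np.exp(-1), abs=0.01)
        # drawn with replacement: duplicates must occur
        assert (uniq < 1.0).all()

    def test_determinism_under_seed(self):
        table = separable_table(n=400, seed=4)
        a = TrendDriverForest(n_trees=50, random_state=9).fit(table)
        b = TrendDriverForest(n_trees=50, random_state=9).fit(table)
        assert a.oob_error_ == b.oob_error_
        np.testing.assert_array_equal(a.bootstrap_indices_, b.bootstrap_indices_)
        pd.testing.assert_series_equal(a.importance_mda(seed=3),
                                       b.importance_mda(seed=3))

    def test_single_class_rejected(self):
        table = separable_table(n=100)
        table["label"] = 1
        with pytest.raises(ValueError, match="2 classes"):
            TrendDriverForest(n_trees=10).fit(table)

    def test_oob_error_bounds_and_votes_shape(self):
        table = separable_table(n=300, seed=5)
        f = TrendDriverForest(n_trees=40, random_state=2).fit(table)
        assert 0.0 <= f.oob_error_ <= 1.0
        assert f.oob_votes_.shape == (300, 2)
        assert f.oob_votes_.sum() <= 40 * 300


class TestImportances:
    def test_planted_driver_ranked_first_by_both_metrics(self):
        table = separable_table(n=800, seed=6)
        f = TrendDriverForest(n_trees=100, random_state=0).fit(table)
        assert f.importance_gini().idxmax() == "driver"
        assert f.importance_mda(seed=0).idxmax() == "driver"

    def test_unused_constant_feature_zero_gini(self):
        table = separable_table(n=400, seed=7)
        table.insert(1, "constant", 1.0)
        f = TrendDriverForest(n_trees=50, random_state=1).fit(table)
        gini = f.importance_gini()
        assert gini["constant"] == 0.0
        assert (gini >= 0).all()
        mda = f.importance_mda(seed=1)
        assert mda["constant"] == 0.0

    def test_duplicated_noise_feature_keeps_driver_on_top(self):
        table = separable_table(n=600, seed=8)
        table["noise_dup"] = table["noise_0"]
        f = TrendDriverForest(n_trees=100, random_state=3).fit(table)
        assert f.importance_mda(seed=2).idxmax() == "driver"

    def test_normalized_max_is_one(self):
        table = separable_table(n=400, seed=9)
        f = TrendDriverForest(n_trees=50, random_state=4).fit(table)
        assert f.importance_gini(normalize=True).max() == pytest.approx(1.0)
        assert f.importance_mda(seed=0, normalize=True).abs().max() == \
            pytest.approx(1.0)

    def test_permutation_seed_required(self):
        table = separable_table(n=200, seed=10)
        f = TrendDriverForest(n_trees=20, random_state=5).fit(table)
        with pytest.raises(ValueError, match="seed"):
            f.importance_mda(seed=None)

    def test_per_class_restriction_runs(self):
        table = separable_table(n=400, seed=11)
        f = TrendDriverForest(n_trees=50, random_state=6).fit(table)
        under = f.importance_mda(seed=0, restrict_class=1)
        over = f.importance_mda(seed=0, restrict_class=-1)
        assert under.idxmax() == "driver" and over.idxmax() == "driver"


class TestCategoricalHandling:
    def test_categorical_feature_drives_separation(self):
        rng = np.random.default_rng(12)
        n = 600
        soil = rng.integers(1, 5, n)
        y = np.where(soil >= 3, 1, -1)
        table = pd.DataFrame({"soil": soil, "noise": rng.normal(size=n),
                              "label": y})
        f = TrendDriverForest(n_trees=60, random_state=0,
                              categorical={"soil"}).fit(table)
        assert f.oob_error_ <= 0.02
        assert f.importance_gini().idxmax() == "soil"


class TestClassHistograms:
    def test_proportions_sum_to_one_within_class(self):
        rng = np.random.default_rng(13)
        table = pd.DataFrame({
            "elevation": rng.normal(1000, 100, 200),
            "label": rng.choice([-2, -1, 1, 2], 200),
        })
        hist = class_histograms(table, n_bins=5, feature_order=["elevation"],
                                categorical=set())
        sums = hist.groupby("class")["proportion"].sum()
        np.testing.assert_allclose(sums, 1.0)

    def test_matches_brute_force_tally(self):
        table = pd.DataFrame({
            "pa": [1, 1, 0, 0, 1, 0],
            "label": [1, 1, 1, -1, -1, -1],
        })
        hist = class_histograms(table, feature_order=["pa"],
                                categorical={"pa"})
        under_pa1 = hist.query("covariate == 'pa' and bin == '1' and `class` == 1")
        assert under_pa1["proportion"].item() == pytest.approx(2 / 3)
        over_pa0 = hist.query("covariate == 'pa' and bin == '0' and `class` == -1")
        assert over_pa0["proportion"].item() == pytest.approx(2 / 3)

    def test_single_class_table(self):
        table = pd.DataFrame({"pa": [1, 0, 1], "label": [1, 1, 1]})
        hist = class_histograms(table, feature_order=["pa"], categorical={"pa"})
        assert set(hist["class"]) == {1}
        assert hist["proportion"].sum() == pytest.approx(1.0)


class TestCombinedExplained:
    def test_published_accounting_identity(self):
        # 57.18% directly explained; 75.2% of the remaining 42.82%
        assert combined_explained(57.18, 75.2) == 89.38
        assert round(100 - 57.18, 2) == 42.82

    def test_degenerate_second_stage(self):
        assert combined_explained(64.2, 0.0) == 64.2

    def test_saturation(self):
        assert combined_explained(100.0, 12.3) == 100.0

    @pytest.mark.parametrize("bad", [(-1, 50), (50, 101)])
    def test_out_of_range(self, bad):
        with pytest.raises(ValueError, match="outside"):
            combined_explained(*bad)
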