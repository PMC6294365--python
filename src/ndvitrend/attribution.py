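"""Driver attribution of the residual trend surface with a random forest.

Points are sampled inside the significantly under-/over-predicted
regions, static social/physical covariates are extracted at those
points, and a bootstrap ensemble of CART trees (Gini splits, grown to
purity, mtry = floor(sqrt(p)) features per split) classifies
under vs over.  The ensemble keeps full bootstrap bookkeeping: per-tree
in-bag row indices, an out-of-bag (OOB) vote matrix, OOB error, per-tree
OOB permutation importance (mean decrease in accuracy, MDA) and raw
Gini importance totals.  Individual trees are grown by
scikit-learn's CART implementation; the bagging, OOB accounting and
importance metrics are owned here.

Categorical covariates are expanded one-hot internally (one-vs-rest
single-category splits); importances are summed back to the parent
covariate before reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier

from .grid import RasterLayer

__all__ = [
    "SamplePlan",
    "sample_points",
    "extract_features",
    "FEATURE_ORDER",
    "TrendDriverForest",
    "majority_vote",
    "class_histograms",
    "combined_explained",
]

#: documented fixed feature order of the attribution table
FEATURE_ORDER = [
    "elevation",
    "slope",
    "aspect",
    "land_cover",
    "soil",
    "country",
    "population",
    "protected_area",
    "inundated",
    "dist_road",
    "dist_settlement",
    "dist_river",
    "within_90m_road",
    "within_90m_river",
    "within_1km_settlement",
]

CATEGORICAL_FEATURES = {
    "land_cover", "soil", "country", "protected_area", "inundated",
    "within_90m_road", "within_90m_river", "within_1km_settlement",
}


@dataclass
class SamplePlan:
    """How many points per class, minimum spacing (cells), and the seed."""

    n_points: int = 1000
    spacing: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.spacing < 0:
            raise ValueError("spacing must be >= 0")


def sample_points(
    class_values: np.ndarray,
    classes,
    plan: SamplePlan,
) -> pd.DataFrame:
    """Seeded random point sample with a minimum-spacing constraint.

    Draws exactly ``plan.n_points`` pixels from each requested class
    (Euclidean spacing in cell units, enforced within a class), erroring
    if a class cannot supply them.
    """
    rng = np.random.default_rng(plan.seed)
    cls = np.asarray(class_values)
    rows_out = []
    for c in classes:
        rr, cc = np.nonzero(cls == c)
        if rr.size == 0:
            raise ValueError(f"class {c} not present in the raster")
        order = rng.permutation(rr.size)
        chosen: list[int] = []
        if plan.spacing == 0:
            chosen = list(order[: plan.n_points])
        else:
            taken_r, taken_c = [], []
            s2 = plan.spacing**2
            for idx in order:
                r, c_ = rr[idx], cc[idx]
                if taken_r:
                    d2 = (np.array(taken_r) - r) ** 2 + (np.array(taken_c) - c_) ** 2
                    if (d2 < s2).any():
                        continue
                chosen.append(idx)
                taken_r.append(r)
                taken_c.append(c_)
                if len(chosen) == plan.n_points:
                    break
        if len(chosen) < plan.n_points:
            raise ValueError(
                f"class {c}: only {len(chosen)} points satisfy the plan "
                f"(requested {plan.n_points}, spacing {plan.spacing})"
            )
        rows_out.append(
            pd.DataFrame({"row": rr[chosen], "col": cc[chosen], "label": c})
        )
    return pd.concat(rows_out, ignore_index=True)


def extract_features(
    points: pd.DataFrame,
    layers: dict[str, RasterLayer],
    feature_order=None,
) -> pd.DataFrame:
    """Build the feature table: one row per point, columns in
    :data:`FEATURE_ORDER`, trend-class label attached.  Points hitting
    nodata in any layer are rejected (reported via a warning)."""
    feature_order = list(feature_order or FEATURE_ORDER)
    missing = [f for f in feature_order if f not in layers]
    if missing:
        raise KeyError(f"missing covariate layers: {missing}")
    r = points["row"].to_numpy()
    c = points["col"].to_numpy()
    table = pd.DataFrame({"row": r, "col": c})
    ok = np.ones(len(points), dtype=bool)
    for name in feature_order:
        layer = layers[name]
        vals = np.asarray(layer.values)[r, c]
        ok &= np.asarray(layer.valid_mask())[r, c]
        table[name] = vals
    table["label"] = points["label"].to_numpy()
    n_rej = int((~ok).sum())
    if n_rej:
        warnings.warn(f"rejected {n_rej} sample point(s) on nodata cells")
    out = table[ok].reset_index(drop=True)
    out.attrs["n_rejected"] = n_rej
    out.attrs["feature_order"] = feature_order
    return out


def majority_vote(votes: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Per-row majority over per-class vote counts; ties go to the
    smallest class code (classes assumed sorted ascending)."""
    return np.asarray(classes)[np.argmax(votes, axis=1)]


class TrendDriverForest(BaseEstimator, ClassifierMixin):
    """Random-forest classifier with explicit bootstrap/OOB bookkeeping.

    Parameters
    ----------
    n_trees : ensemble size (default 500).
    mtry : features tried per split; None = floor(sqrt(n_features)).
    min_leaf : minimum samples per leaf (trees grow to purity by default,
        unpruned).
    random_state : seed; fixes the bootstrap draws and tree randomness.
    categorical : names of columns to one-hot encode; None = the
        package's standard roster intersected with the columns.

    Fitted attributes
    -----------------
    classes_, feature_names_, bootstrap_indices_ (n_trees, n_rows),
    oob_votes_ (n_rows, n_classes), oob_prediction_, oob_error_,
    oob_accuracy_, never_oob_ (bool mask).
    """

    def __init__(
        self,
        n_trees: int = 500,
        mtry: int | None = None,
        min_leaf: int = 1,
        random_state: int | None = None,
        categorical=None,
    ):
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_leaf = min_leaf
        self.random_state = random_state
        self.categorical = categorical

    # ------------------------------------------------------------------
    def _encode(self, X: pd.DataFrame) -> np.ndarray:
        mats = []
        self._col_feature = []  # parent feature of each encoded column
        for name in self.feature_names_:
            col = X[name].to_numpy()
            if name in self._categorical:
                for code in self._category_codes[name]:
                    mats.append((col == code).astype(float))
                    self._col_feature.append(name)
            else:
                mats.append(col.astype(float))
                self._col_feature.append(name)
        return np.column_stack(mats)

    def fit(self, X: pd.DataFrame, y=None):
        if y is None:
            if "label" not in X.columns:
                raise ValueError("either pass y or include a 'label' column")
            y = X["label"].to_numpy()
        X = X.drop(columns=[c for c in ("label", "row", "col") if c in X.columns])
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes to fit the forest")
        counts = pd.Series(y).value_counts()
        if (counts < 10).any():
            warnings.warn("fewer than 10 rows in some class; OOB estimates noisy")
        self.feature_names_ = list(X.columns)
        self._categorical = (
            set(self.categorical)
            if self.categorical is not None
            else CATEGORICAL_FEATURES & set(self.feature_names_)
        )
        self._category_codes = {
            name: np.unique(X[name].to_numpy()) for name in self._categorical
        }
        Xe = self._encode(X)
        n, p_enc = Xe.shape
        y_idx = np.searchsorted(self.classes_, y)
        mtry = self.mtry or max(1, int(np.sqrt(len(self.feature_names_))))
        mtry = min(mtry, p_enc)

        rng = np.random.default_rng(self.random_state)
        self.trees_ = []
        self.bootstrap_indices_ = np.empty((self.n_trees, n), dtype=np.int64)
        self.oob_votes_ = np.zeros((n, self.classes_.size), dtype=np.int64)
        self._oob_masks = np.zeros((self.n_trees, n), dtype=bool)
        for t in range(self.n_trees):
            idx = rng.integers(0, n, n)
            self.bootstrap_indices_[t] = idx
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            self._oob_masks[t] = oob
            tree = DecisionTreeClassifier(
                criterion="gini",
                max_features=mtry,
                min_samples_leaf=self.min_leaf,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(Xe[idx], y_idx[idx])
            self.trees_.append(tree)
            if oob.any():
                pred = tree.predict(Xe[oob]).astype(int)
                np.add.at(self.oob_votes_, (np.nonzero(oob)[0], pred), 1)

        self._X_encoded = Xe
        self._y_idx = y_idx
        self.never_oob_ = self.oob_votes_.sum(axis=1) == 0
        if self.never_oob_.any():
            warnings.warn(
                f"{int(self.never_oob_.sum())} row(s) never out-of-bag; "
                "excluded from the OOB error"
            )
        used = ~self.never_oob_
        oob_pred_idx = np.argmax(self.oob_votes_, axis=1)
        self.oob_prediction_ = self.classes_[oob_pred_idx]
        self.oob_error_ = float(
            (oob_pred_idx[used] != y_idx[used]).mean()
        )
        self.oob_accuracy_ = 1.0 - self.oob_error_
        return self

    # ------------------------------------------------------------------
    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "trees_"):
            raise AttributeError("forest is not fitted")
        X = X.drop(columns=[c for c in ("label", "row", "col") if c in X.columns])
        if list(X.columns) != self.feature_names_:
            raise ValueError("feature columns differ from the fitted table")
        if X.isna().to_numpy().any():
            raise ValueError("missing feature values in prediction rows")
        Xe = self._encode(X)
        votes = np.zeros((len(X), self.classes_.size), dtype=np.int64)
        for tree in self.trees_:
            pred = tree.predict(Xe).astype(int)
            np.add.at(votes, (np.arange(len(X)), pred), 1)
        return majority_vote(votes, self.classes_)

    # ------------------------------------------------------------------
    def importance_gini(self, normalize: bool = False) -> pd.Series:
        """Total Gini impurity decrease per covariate, summed over every
        split of every tree (weighted by node sample fraction)."""
        p_enc = self._X_encoded.shape[1]
        total = np.zeros(p_enc)
        for tree in self.trees_:
            total += tree.tree_.compute_feature_importances(normalize=False)
        out = pd.Series(0.0, index=self.feature_names_)
        for j, parent in enumerate(self._col_feature):
            out[parent] += total[j]
        if normalize and out.max() > 0:
            out = out / out.max()
        return out

    def importance_mda(
        self,
        seed: int | None = 0,
        normalize: bool = False,
        restrict_class=None,
    ) -> pd.Series:
        """Mean decrease in accuracy: per tree, OOB accuracy minus OOB
        accuracy with the covariate's values permuted (all one-hot
        columns of a categorical permuted jointly), averaged over trees.

        ``restrict_class`` limits the accuracy to rows of one true class
        (the per-class importance view).
        """
        if seed is None:
            raise ValueError("a permutation seed is required for reproducibility")
        rng = np.random.default_rng(seed)
        Xe = self._X_encoded
        y = self._y_idx
        drops = np.zeros(len(self.feature_names_))
        n_used = np.zeros(len(self.feature_names_))
        col_groups = [
            [j for j, parent in enumerate(self._col_feature) if parent == name]
            for name in self.feature_names_
        ]
        for tree, oob in zip(self.trees_, self._oob_masks):
            rows = np.nonzero(oob)[0]
            if rows.size == 0:
                continue
            if restrict_class is not None:
                score = y[rows] == np.searchsorted(self.classes_, restrict_class)
                if not score.any():
                    continue
            else:
                score = np.ones(rows.size, dtype=bool)
            base_acc = float(
                (tree.predict(Xe[rows]).astype(int) == y[rows])[score].mean()
            )
            # permute across *all* OOB rows (then score the restricted
            # subset) so within-class structure is genuinely broken
            perm = rng.permutation(rows.size)
            for f, cols in enumerate(col_groups):
                Xp = Xe[rows].copy()
                Xp[:, cols] = Xp[np.ix_(perm, cols)]
                acc = float(
                    (tree.predict(Xp).astype(int) == y[rows])[score].mean()
                )
                drops[f] += base_acc - acc
                n_used[f] += 1
        out = pd.Series(
            np.where(n_used > 0, drops / np.maximum(n_used, 1), 0.0),
            index=self.feature_names_,
        )
        if normalize and out.abs().max() > 0:
            out = out / out.abs().max()
        return out

    def summary(self) -> dict:
        per_class_err = {}
        used = ~self.never_oob_
        for k, c in enumerate(self.classes_):
            rows = used & (self._y_idx == k)
            if rows.any():
                per_class_err[str(c)] = float(
                    (np.argmax(self.oob_votes_[rows], axis=1) != k).mean()
                )
        return {
            "n_trees": int(self.n_trees),
            "mtry": self.mtry or int(np.sqrt(len(self.feature_names_))),
            "random_state": self.random_state,
            "oob_error": self.oob_error_,
            "oob_accuracy": self.oob_accuracy_,
            "per_class_oob_error": per_class_err,
            "classes": [int(c) for c in self.classes_],
            "features": self.feature_names_,
        }


# ---------------------------------------------------------------------------


def class_histograms(
    table: pd.DataFrame,
    n_bins: int = 10,
    feature_order=None,
    categorical=None,
) -> pd.DataFrame:
    """Per-covariate, per-class bin proportions (the four-way histogram
    view).  Within each class the proportions over bins sum to 1; empty
    classes are omitted with a warning."""
    feature_order = list(
        feature_order or table.attrs.get("feature_order") or
        [c for c in table.columns if c not in ("row", "col", "label")]
    )
    categorical = set(categorical) if categorical is not None else CATEGORICAL_FEATURES
    classes = [c for c in sorted(table["label"].unique())]
    rows = []
    for feat in feature_order:
        vals = table[feat]
        if feat in categorical:
            bins = sorted(vals.unique())
            binned = vals
            labels = [str(b) for b in bins]
        else:
            edges = np.linspace(vals.min(), vals.max(), n_bins + 1)
            edges[-1] += 1e-9
            binned = pd.Series(
                np.digitize(vals, edges[1:-1]), index=table.index
            )
            bins = list(range(n_bins))
            labels = [f"[{edges[i]:.4g}, {edges[i+1]:.4g})" for i in bins]
        for cls in classes:
            sub = binned[table["label"] == cls]
            if len(sub) == 0:
                warnings.warn(f"class {cls} empty for covariate {feat}; omitted")
                continue
            counts = sub.value_counts()
            for b, lab in zip(bins, labels):
                rows.append(
                    {
                        "covariate": feat,
                        "bin": lab,
                        "class": cls,
                        "proportion": counts.get(b, 0) / len(sub),
                    }
                )
    return pd.DataFrame(rows)


def combined_explained(correct_pct: float, rf_accuracy_pct: float) -> float:
    """Landscape fraction explained by the two stages combined:
    correct + rf_accuracy * (100 - correct) / 100, as a percentage."""
    for v in (correct_pct, rf_accuracy_pct):
        if not 0 <= v <= 100:
            raise ValueError(f"percentage {v} outside [0, 100]")
    return round(correct_pct + rf_accuracy_pct * (100.0 - correct_pct) / 100.0, 2)
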