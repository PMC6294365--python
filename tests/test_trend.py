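"""Seasonal Mann-Kendall, Sen's slope, residual differencing, classing."""

import itertools

import numpy as np
import pytest
from scipy import stats

from ndvitrend.grid import Grid, PolygonPartition, PolygonSeriesMatrix, RasterStack
from ndvitrend.trend import (
    CLASS_NAMES,
    ResidualTrendAnalysis,
    classify,
    difference,
    mk_month,
    seasonal_mk,
    sens_slope,
    summarize,
    trend_stats,
)

# ---------------------------------------------------------------------------
# brute-force oracles


def brute_s_var(values):
    """Kendall S and tie-corrected variance by direct enumeration."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    n = len(v)
    if n < 2:
        return 0, 0.0
    s = sum(np.sign(v[j] - v[k]) for k in range(n) for j in range(k + 1, n))
    ties = {}
    for val in v:
        ties[val] = ties.get(val, 0) + 1
    tie_term = sum(t * (t - 1) * (2 * t + 5) for t in ties.values())
    return int(s), (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0


def brute_sens(series, period=12):
    """All-pairs/median Sen's slope oracle."""
    v = np.asarray(series, dtype=float)
    betas = []
    for m in range(period):
        month = v[m::period]
        idx = [j for j in range(len(month)) if not np.isnan(month[j])]
        if len(idx) < 2:
            continue
        slopes = [
            (month[j] - month[k]) / (j - k)
            for k, j in itertools.combinations(idx, 2)
        ]
        betas.append(np.median(slopes))
    return np.median(betas) if betas else np.nan


class TestMkMonth:
    def test_three_increasing_values(self):
        s, var = mk_month([1.0, 2.0, 3.0])
        assert s == 3
        assert var == pytest.approx(66 / 18)

    def test_all_tied(self):
        s, var = mk_month([2.0, 2.0, 2.0])
        assert s == 0 and var == 0.0

    def test_antisymmetry(self):
        v = np.random.default_rng(0).normal(size=8)
        s1, var1 = mk_month(v)
        s2, var2 = mk_month(v[::-1])
        assert s2 == -s1 and var2 == var1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.integers(0, 4, size=10).astype(float)
        v[rng.integers(0, 10)] = np.nan
        assert mk_month(v) == brute_s_var(v)

    def test_short_series_contributes_nothing(self):
        assert mk_month([1.0]) == (0, 0.0)
        assert mk_month([np.nan, 2.0]) == (0, 0.0)


class TestSeasonalMk:
    def test_perfect_concordance(self):
        series = np.concatenate([np.arange(12) + 20 * y for y in range(5)])
        tau, z, p = seasonal_mk(series.astype(float))
        assert tau == pytest.approx(1.0)
        assert p < 0.01

    def test_no_information(self):
        tau, z, p = seasonal_mk(np.full(36, 3.0))
        assert (tau, z, p) == (0.0, 0.0, 1.0)

    def test_translation_and_scale_invariance(self):
        rng = np.random.default_rng(1)
        series = rng.normal(size=120)
        base = seasonal_mk(series)
        shifted = seasonal_mk(series + 5.3)
        scaled = seasonal_mk(series * 2.7)
        assert shifted == pytest.approx(base)
        assert scaled == pytest.approx(base)
        assert sens_slope(series + 5.3) == pytest.approx(sens_slope(series))
        assert sens_slope(series * 2.7) == pytest.approx(2.7 * sens_slope(series))

    def test_single_season_equals_plain_mann_kendall(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=9)
        tau1, z1, p1 = seasonal_mk(v, period=1)
        s, var = mk_month(v)
        assert z1 == pytest.approx(s / np.sqrt(var))
        _, z1c, _ = seasonal_mk(v, period=1, continuity=True)
        assert z1c == pytest.approx((s - np.sign(s)) / np.sqrt(var))
        # tau matches scipy's tau-b against the time index
        tau_ref = stats.kendalltau(np.arange(9), v).statistic
        assert tau1 == pytest.approx(tau_ref)

    def test_normal_p_close_to_exact_permutation_n5(self):
        """n = 5 single season: enumerate all 120 orderings for the exact
        two-sided p of |S|.  The continuity-corrected normal p (the
        small-sample option) tracks it closely; the default uncorrected p
        sits within the known normal-approximation error at this n."""
        v = np.array([0.1, 0.3, 0.2, 0.5, 0.4])
        s_obs, _ = mk_month(v)
        perms = [brute_s_var(np.array(p))[0]
                 for p in itertools.permutations(v)]
        exact_p = np.mean([abs(s) >= abs(s_obs) for s in perms])
        _, _, p_corr = seasonal_mk(v, period=1, continuity=True)
        assert p_corr == pytest.approx(exact_p, abs=0.05)
        _, _, p_default = seasonal_mk(v, period=1)
        assert p_default == pytest.approx(exact_p, abs=0.12)


class TestSensSlope:
    def test_single_month_three_years(self):
        series = np.full(36, np.nan)
        series[[0, 12, 24]] = [0.2, 0.3, 0.5]
        # pair slopes {0.1, 0.15, 0.2} -> median 0.15
        assert sens_slope(series) == pytest.approx(0.15)

    def test_identical_month_slopes(self):
        years = np.arange(3)
        series = np.concatenate([0.15 * y + np.arange(12) * 0.0 for y in years])
        assert sens_slope(series) == pytest.approx(0.15)

    def test_exact_line_recovers_slope(self):
        t = np.arange(120)
        b = 0.042
        series = 1.0 + b * (t / 12.0)
        assert sens_slope(series) == pytest.approx(b, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        series = rng.normal(size=60)
        series[rng.integers(0, 60, size=6)] = np.nan
        got = sens_slope(series)
        want = brute_sens(series)
        assert got == pytest.approx(want, abs=1e-15)

    def test_matches_scipy_theilslopes_per_month(self):
        rng = np.random.default_rng(3)
        month_vals = rng.normal(size=8)
        series = np.full(8 * 12, np.nan)
        series[::12] = month_vals  # single month populated
        ref = stats.theilslopes(month_vals, np.arange(8)).slope
        assert sens_slope(series) == pytest.approx(ref)

    def test_undefined_when_no_month_qualifies(self):
        series = np.full(24, np.nan)
        series[0] = 1.0
        assert np.isnan(sens_slope(series))


def test_vectorized_matches_scalar_functions():
    rng = np.random.default_rng(4)
    mat = rng.normal(size=(40, 120))
    mat[rng.random(mat.shape) < 0.08] = np.nan
    mat[5] = np.round(mat[5], 1)  # force ties
    out = trend_stats(mat)
    for i in range(40):
        tau, z, p = seasonal_mk(mat[i])
        assert out["tau"][i] == pytest.approx(tau, abs=1e-12)
        assert out["z"][i] == pytest.approx(z, abs=1e-12)
        assert out["p"][i] == pytest.approx(p, abs=1e-12)
        beta = sens_slope(mat[i])
        if np.isnan(beta):
            assert np.isnan(out["beta"][i])
        else:
            assert out["beta"][i] == pytest.approx(beta, abs=1e-12)


def test_type_one_error_rough_calibration():
    """White-noise null at alpha = 0.1 rejects near nominally (quick
    check; the tighter binomial-band calibration runs in acceptance)."""
    rng = np.random.default_rng(10)
    mat = rng.normal(size=(500, 120))
    out = trend_stats(mat)
    rate = (out["p"] <= 0.1).mean()
    assert 0.06 <= rate <= 0.14


class TestDifference:
    def _setup(self):
        g = Grid(2, 2, 30.0)
        labels = np.array([[1, 1], [2, 2]])
        part = PolygonPartition(grid=g, labels=labels, n_polygons=2)
        ta = [(2001, m) for m in (1, 2)]
        pred = PolygonSeriesMatrix(
            values=np.array([[0.4, 0.5], [0.2, 0.3]]),
            polygon_ids=[1, 2], time_axis=ta,
        )
        obs_vals = np.empty((2, 2, 2))
        obs_vals[0] = [[0.4, 0.4], [0.2, 0.2]]
        obs_vals[1] = [[0.5, 0.5], [0.3, 0.3]]
        obs = RasterStack(grid=g, values=obs_vals, time_axis=ta)
        return g, part, pred, obs

    def test_identity_and_shift(self):
        g, part, pred, obs = self._setup()
        resid = difference(obs, pred, part)
        np.testing.assert_allclose(resid.values, 0.0)
        pred.values[1] += 0.1  # shift polygon 2 predictions
        resid2 = difference(obs, pred, part)
        np.testing.assert_allclose(resid2.values[:, 0, :], 0.0)
        np.testing.assert_allclose(resid2.values[:, 1, :], -0.1)

    def test_nodata_propagates(self):
        g, part, pred, obs = self._setup()
        obs.values[0, 0, 0] = np.nan
        resid = difference(obs, pred, part)
        assert np.isnan(resid.values[0, 0, 0])
        assert np.isfinite(resid.values[1, 0, 0])

    def test_time_axis_mismatch(self):
        g, part, pred, obs = self._setup()
        pred.time_axis = [(2002, 1), (2002, 2)]
        with pytest.raises(ValueError, match="time axes"):
            difference(obs, pred, part)

    def test_missing_polygon_error(self):
        g, part, pred, obs = self._setup()
        pred2 = PolygonSeriesMatrix(
            values=pred.values[:1], polygon_ids=[1], time_axis=obs.time_axis
        )
        with pytest.raises(ValueError, match="absent"):
            difference(obs, pred2, part)


class TestClassify:
    def test_signs_and_alpha(self):
        tau = np.array([0.4, -0.4, 0.4, 0.2])
        p = np.array([0.05, 0.05, 0.5, 0.05])
        cls = classify(tau, p, alpha=0.1, extreme=999.0)
        assert cls[0] == 1  # under-prediction: observed trending above
        assert cls[1] == -1
        assert cls[2] == 0
        assert cls[3] == 1

    def test_alpha_zero_all_none(self):
        tau = np.array([0.9, -0.9])
        p = np.array([0.001, 0.001])
        assert np.all(classify(tau, p, alpha=0.0) == 0)

    def test_group_median_promotes_extremes(self):
        tau = np.array([0.2, 0.4, 0.6, 0.8, -0.3, -0.7])
        p = np.full(6, 0.01)
        cls = classify(tau, p, alpha=0.1, extreme="group_median")
        assert list(cls[:4]) == [1, 1, 2, 2]  # >= group median promoted
        assert list(cls[4:]) == [-1, -2]

    def test_float_extreme_rule(self):
        tau = np.array([0.3, 0.9])
        p = np.array([0.01, 0.01])
        cls = classify(tau, p, alpha=0.1, extreme=0.8)
        assert list(cls) == [1, 2]


class TestSummarize:
    def test_all_none(self):
        s = summarize(np.zeros((5, 5), dtype=int))
        assert s["none"] == 100.0
        assert s["correct_pct"] == 100.0

    def test_closure_and_counts(self):
        rng = np.random.default_rng(6)
        cls = rng.choice([-2, -1, 0, 1, 2], size=(40, 40))
        s = summarize(cls)
        total = sum(s[name] for name in CLASS_NAMES.values())
        assert total == pytest.approx(100.0, abs=0.02)
        assert s["changed_sum"] == pytest.approx(
            s["changed_complement"], abs=0.03
        )

    def test_zero_valid_error(self):
        with pytest.raises(ValueError, match="no valid"):
            summarize(np.zeros((2, 2)), valid=np.zeros((2, 2), dtype=bool))


def test_residual_trend_analysis_end_to_end_object():
    """Planted linear drifts on a toy stack come back with the right
    classes and slope estimates."""
    g = Grid(6, 6, 30.0)
    T = 120
    rng = np.random.default_rng(8)
    base = rng.normal(0, 0.03, size=(T, 6, 6))
    t = (np.arange(T) / 12.0)[:, None, None]
    slopes = np.zeros((6, 6))
    slopes[:2] = 0.05   # strong upward: under-prediction
    slopes[4:] = -0.05  # strong downward
    vals = base + slopes[None] * t
    vals[:, 3, 3] = np.nan
    stack = RasterStack(grid=g, values=vals,
                        time_axis=[(2001 + i // 12, i % 12 + 1) for i in range(T)])
    rta = ResidualTrendAnalysis(alpha=0.1).fit(stack)
    assert np.all(rta.classes_[:2] > 0)
    assert np.all(rta.classes_[4:] < 0)
    assert not rta.valid_[3, 3]
    np.testing.assert_allclose(rta.beta_[0], 0.05, atol=0.02)
    layer = rta.class_layer()
    assert layer.values[3, 3] == -99
    assert rta.summary_["under_total"] >= 30.0
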