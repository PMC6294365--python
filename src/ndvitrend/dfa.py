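"""Dynamic factor analysis of polygon-level NDVI series.

Model (per time step t, on per-series standardized data):

    y_t = mu + Gamma * alpha_t + D * x_t + eps_t,   eps_t ~ N(0, diag(R))
    alpha_t = alpha_{t-1} + eta_t,                  eta_t ~ N(0, I_M)

with N observed series (polygons), M random-walk common trends, and K
explanatory covariate series.  This is the canonical identifiable
"common trends + explanatory variables" parameterization: identity
state noise, diagonal observation covariance, loadings Gamma with zeros
strictly above the diagonal and non-negative diagonal.

Estimation is EM: the E-step runs a Kalman filter/smoother (information
form exploiting the diagonal R, so each update costs O(N M^2) and the
log-likelihood comes from the prediction-error decomposition via the
matrix determinant lemma); the M-step is an exact generalized least
squares update of (Gamma, D, mu, R) row by row, which makes the
log-likelihood non-decreasing at every iteration.  Missing observations
are simply skipped in both steps (no imputation).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from ._kalman import filter_smoother
from .grid import PolygonSeriesMatrix

__all__ = [
    "DynamicFactorAnalysis",
    "standardize",
    "fit_dfa",
    "aic",
    "select_model",
]


def standardize(series) -> tuple[np.ndarray, dict]:
    """Per-series standardization to mean 0, sd 1 over non-missing entries.

    Returns the standardized matrix and ``{"mean": ..., "scale": ...}``
    for the back-transform.  Raises on constant series, naming the
    offending polygon.
    """
    ids = None
    if isinstance(series, PolygonSeriesMatrix):
        ids = series.polygon_ids
        y = series.values
    else:
        y = np.asarray(series, dtype=float)
    mean = np.nanmean(y, axis=1)
    scale = np.nanstd(y, axis=1)
    bad = np.flatnonzero(scale <= 1e-12 * np.maximum(1.0, np.abs(mean)))
    if bad.size:
        names = [ids[i] if ids else i for i in bad]
        raise ValueError(
            f"constant (zero-variance) series for polygon(s) {names}; "
            "cannot standardize"
        )
    n_obs = np.sum(~np.isnan(y), axis=1)
    if np.any(n_obs < 2):
        raise ValueError("each series needs at least 2 non-missing values")
    std = (y - mean[:, None]) / scale[:, None]
    return std, {"mean": mean, "scale": scale}


class DynamicFactorAnalysis(BaseEstimator):
    """EM-estimated dynamic factor model producing polygon-level NDVI_pred.

    Parameters
    ----------
    n_trends : number of random-walk common trends (M); 0 reduces the
        model to per-series OLS on the covariates.
    tol : EM stops when the log-likelihood improves by less than this.
    max_iter : EM iteration cap.
    standardize : standardize each series before fitting and fold the
        transform back into :meth:`predict`.
    initial_state_var : variance of the diffuse-ish alpha_0 prior.
    min_variance : floor for the observation variances R.
    n_starts : extra EM runs from jittered loading initializations; the
        best likelihood wins (run 0 is always the deterministic start).
    random_state : seed for the jittered restarts.
    """

    def __init__(
        self,
        n_trends: int = 2,
        tol: float = 1e-6,
        max_iter: int = 2000,
        standardize: bool = True,
        initial_state_var: float = 5.0,
        min_variance: float = 1e-8,
        n_starts: int = 1,
        random_state: int | None = None,
    ):
        self.n_trends = n_trends
        self.tol = tol
        self.max_iter = max_iter
        self.standardize = standardize
        self.initial_state_var = initial_state_var
        self.min_variance = min_variance
        self.n_starts = n_starts
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, y, X=None):
        """Fit to ``y`` (N x T series matrix, NaN = missing) with optional
        covariates ``X`` (K x T, complete)."""
        self.time_axis_ = None
        self.polygon_ids_ = None
        if isinstance(y, PolygonSeriesMatrix):
            self.time_axis_ = y.time_axis
            self.polygon_ids_ = list(y.polygon_ids)
            y = y.values
        y = np.asarray(y, dtype=float)
        if y.ndim != 2:
            raise ValueError("y must be an (n_series, n_times) matrix")
        N, T = y.shape
        M = int(self.n_trends)
        if M >= N:
            raise ValueError(
                f"n_trends={M} >= n_series={N}: model not identifiable"
            )
        if X is None:
            x = np.zeros((0, T))
        else:
            x = np.atleast_2d(np.asarray(X, dtype=float))
            if x.shape[1] != T:
                raise ValueError(f"covariates have {x.shape[1]} times, y has {T}")
        K = x.shape[0]
        if T <= K + M:
            raise ValueError("need more time steps than covariates + trends")

        if self.standardize:
            ys, params = standardize(y)
            self.mean_, self.scale_ = params["mean"], params["scale"]
        else:
            ys = y.copy()
            self.mean_ = np.zeros(N)
            self.scale_ = np.ones(N)

        if M == 0:
            self._fit_ols(ys, x)
        else:
            self._fit_em(ys, x)

        self.n_series_ = N
        self.n_covariates_ = K
        self.x_ = x
        self.n_params_ = int(N * M - M * (M - 1) // 2 + N * K + N + N)
        self.aic_ = -2.0 * self.loglik_ + 2.0 * self.n_params_
        return self

    # ------------------------------------------------------------------
    def _fit_ols(self, ys: np.ndarray, x: np.ndarray) -> None:
        """Zero-trend reduction: per-series OLS of y on [1, x]."""
        N, T = ys.shape
        K = x.shape[0]
        self.coef_ = np.zeros((N, K))
        self.intercept_ = np.zeros(N)
        self.obs_variance_ = np.zeros(N)
        ll = 0.0
        design_full = np.column_stack([np.ones(T), x.T])
        for i in range(N):
            obs = ~np.isnan(ys[i])
            design = design_full[obs]
            beta, *_ = np.linalg.lstsq(design, ys[i, obs], rcond=None)
            self.intercept_[i] = beta[0]
            self.coef_[i] = beta[1:]
            resid = ys[i, obs] - design @ beta
            n = obs.sum()
            var = max(float(resid @ resid) / n, self.min_variance)
            self.obs_variance_[i] = var
            ll += -0.5 * (n * np.log(2 * np.pi * var) + float(resid @ resid) / var)
        self.loadings_ = np.zeros((N, 0))
        self.states_ = np.zeros((0, T))
        self.states_cov_ = np.zeros((T, 0, 0))
        self.loglik_ = float(ll)
        self.loglik_path_ = [float(ll)]
        self.n_iter_ = 0
        self.converged_ = True

    # ------------------------------------------------------------------
    def _fit_em(self, ys: np.ndarray, x: np.ndarray) -> None:
        N, T = ys.shape
        M = int(self.n_trends)
        K = x.shape[0]
        rng = np.random.default_rng(self.random_state)

        # deterministic initialization: OLS for (mu, D, R); loadings from a
        # PCA of the OLS residuals (projected onto the lower triangle),
        # which starts EM near the dominant shared-variation directions
        free = np.tril(np.ones((N, M), dtype=bool), k=0)
        init_coef = np.zeros((N, K))
        init_mu = np.zeros(N)
        init_var = np.ones(N)
        resid0 = np.zeros((N, T))
        design_full = np.column_stack([np.ones(T), x.T])
        for i in range(N):
            obs = ~np.isnan(ys[i])
            beta, *_ = np.linalg.lstsq(design_full[obs], ys[i, obs], rcond=None)
            init_mu[i] = beta[0]
            init_coef[i] = beta[1:]
            r = ys[i, obs] - design_full[obs] @ beta
            resid0[i, obs] = r
            init_var[i] = max(float(r @ r) / obs.sum(), 1e-3)
        U, sv, _ = np.linalg.svd(resid0, full_matrices=False)
        gamma_pca = U[:, :M] * sv[:M] / np.sqrt(T)
        for j in range(M):  # deterministic sign convention
            if gamma_pca[np.argmax(np.abs(gamma_pca[:, j])), j] < 0:
                gamma_pca[:, j] *= -1

        best = None
        for start in range(max(1, int(self.n_starts))):
            gamma0 = np.where(free, gamma_pca, 0.0)
            if start > 0:
                gamma0 = gamma0 + np.where(free, rng.normal(0, 0.1, (N, M)), 0.0)
            result = self._em_run(
                ys, x, gamma0, init_coef.copy(), init_mu.copy(), init_var.copy()
            )
            if best is None or result["loglik"] > best["loglik"]:
                best = result

        # identifiability: flip factor signs so diag(Gamma) >= 0
        gamma, states, covs = best["gamma"], best["states"], best["covs"]
        for j in range(min(M, N)):
            if gamma[j, j] < 0:
                gamma[:, j] *= -1
                states[j, :] *= -1
                covs[:, j, :] *= -1
                covs[:, :, j] *= -1
        self.loadings_ = gamma
        self.coef_ = best["coef"]
        self.intercept_ = best["mu"]
        self.obs_variance_ = best["var"]
        self.states_ = states
        self.states_cov_ = covs
        self.loglik_ = best["loglik"]
        self.loglik_path_ = best["path"]
        self.n_iter_ = best["n_iter"]
        self.converged_ = best["converged"]

    def _em_run(self, ys, x, gamma, coef, mu, var) -> dict:
        N, T = ys.shape
        M = gamma.shape[1]
        path: list[float] = []
        prev_ll = -np.inf
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            ll, ahat, vhat = self._e_step(ys, x, gamma, coef, mu, var)
            if not np.isfinite(ll):
                raise FloatingPointError(
                    f"EM diverged (non-finite likelihood) at iteration {it}; "
                    f"trace: {path[-5:]}"
                )
            path.append(float(ll))
            if ll + 1e-9 < prev_ll:  # EM guarantee, numerical slack only
                raise FloatingPointError(
                    f"likelihood decreased at iteration {it}: {prev_ll} -> {ll}"
                )
            if abs(ll - prev_ll) < self.tol:
                converged = True
                break
            prev_ll = ll
            gamma, coef, mu, var = self._m_step(ys, x, ahat, vhat, gamma.shape[1])
        return {
            "gamma": gamma, "coef": coef, "mu": mu, "var": var,
            "states": ahat, "covs": vhat, "loglik": path[-1], "path": path,
            "n_iter": it, "converged": converged,
        }

    # ------------------------------------------------------------------
    def _e_step(self, ys, x, gamma, coef, mu, var):
        """Kalman filter + RTS smoother; returns (loglik, a_hat, V_hat)."""
        offset = mu[:, None] + coef @ x  # (N, T)
        return filter_smoother(
            ys, offset, gamma, var, float(self.initial_state_var)
        )

    # ------------------------------------------------------------------
    def _m_step(self, ys, x, ahat, vhat, M):
        """Exact row-wise GLS update of (Gamma, D, mu, R)."""
        N, T = ys.shape
        K = x.shape[0]
        gamma = np.zeros((N, M))
        coef = np.zeros((N, K))
        mu = np.zeros(N)
        var = np.zeros(N)
        A = ahat.T  # (T, M) smoothed means
        for i in range(N):
            mi = min(i + 1, M)
            obs = ~np.isnan(ys[i])
            idx = np.flatnonzero(obs)
            W = np.column_stack([A[idx, :mi], x[:, idx].T, np.ones(idx.size)])
            G = W.T @ W
            # add the smoothing covariance to the factor block
            G[:mi, :mi] += vhat[idx][:, :mi, :mi].sum(axis=0)
            b = W.T @ ys[i, idx]
            beta = np.linalg.solve(G, b)
            gamma[i, :mi] = beta[:mi]
            coef[i] = beta[mi:mi + K]
            mu[i] = beta[-1]
            resid = ys[i, idx] - W @ beta
            extra = np.einsum(
                "m,tmn,n->t", beta[:mi], vhat[idx][:, :mi, :mi], beta[:mi]
            )
            var[i] = max(
                float((resid**2).sum() + extra.sum()) / idx.size,
                self.min_variance,
            )
        return gamma, coef, mu, var

    # ------------------------------------------------------------------
    def predict(self) -> PolygonSeriesMatrix | np.ndarray:
        """Fitted values mu + Gamma*alpha_hat + D*x, back on the NDVI scale."""
        if not hasattr(self, "loglik_"):
            raise AttributeError("model is not fitted; call fit() first")
        fitted = (
            self.intercept_[:, None]
            + self.loadings_ @ self.states_
            + self.coef_ @ self.x_
        )
        fitted = fitted * self.scale_[:, None] + self.mean_[:, None]
        if not np.all(np.isfinite(fitted)):
            raise FloatingPointError("non-finite values in DFA predictions")
        if self.time_axis_ is not None:
            return PolygonSeriesMatrix(
                values=fitted,
                polygon_ids=self.polygon_ids_,
                time_axis=self.time_axis_,
            )
        return fitted

    def summary(self) -> dict:
        """JSON-serializable fit report."""
        return {
            "n_series": self.n_series_,
            "n_trends": int(self.n_trends),
            "n_covariates": self.n_covariates_,
            "loglik": self.loglik_,
            "aic": self.aic_,
            "n_params": self.n_params_,
            "n_iter": self.n_iter_,
            "converged": bool(self.converged_),
            "final_delta": (
                abs(self.loglik_path_[-1] - self.loglik_path_[-2])
                if len(self.loglik_path_) > 1
                else 0.0
            ),
            "intercepts": self.intercept_.tolist(),
            "loadings": self.loadings_.tolist(),
            "coefficients": self.coef_.tolist(),
            "observation_variances": self.obs_variance_.tolist(),
        }


def fit_dfa(y, x=None, m_trends: int = 2, **kwargs) -> DynamicFactorAnalysis:
    """Functional wrapper over :class:`DynamicFactorAnalysis`."""
    return DynamicFactorAnalysis(n_trends=m_trends, **kwargs).fit(y, x)


def aic(model: DynamicFactorAnalysis) -> float:
    """-2 loglik + 2p, with p counting free loadings + coefficients +
    intercepts + observation variances."""
    return float(model.aic_)


def select_model(
    y,
    x=None,
    m_candidates=(0, 1, 2, 3),
    covariate_subsets=None,
    **kwargs,
) -> DynamicFactorAnalysis:
    """Fit all (m_trends, covariate subset) candidates; return the
    minimum-AIC model, breaking ties toward fewer parameters."""
    if covariate_subsets is None:
        covariate_subsets = [None]
    candidates = [(m, sub) for m in m_candidates for sub in covariate_subsets]
    if not candidates:
        raise ValueError("no candidate models supplied")
    fits, failures = [], []
    for m, sub in candidates:
        xs = x
        if sub is not None and x is not None:
            xs = np.asarray(x)[list(sub), :]
        try:
            fits.append(fit_dfa(y, xs, m_trends=m, **kwargs))
        except Exception as exc:  # noqa: BLE001 - aggregated below
            failures.append(f"(m={m}, subset={sub}): {exc}")
    if not fits:
        raise RuntimeError(
            "all candidate DFA fits failed:\n" + "\n".join(failures)
        )
    fits.sort(key=lambda f: (f.aic_, f.n_params_))
    return fits[0]
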