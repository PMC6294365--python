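"""Kalman filter + RTS smoother kernel for the random-walk factor model.

Information-form measurement update exploiting the diagonal observation
covariance: per time step the cost is O(N M^2 + M^3).  The log-likelihood
uses the prediction-error decomposition via the matrix determinant lemma,
    log|F_t| = sum log R_o + log|P_pred| + log|S|,   S = P_pred^-1 + C.

Compiled with numba when available (the EM loop calls this thousands of
times); the pure-NumPy path is identical.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dep in practice
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap(args[0]) if args and callable(args[0]) else wrap


_LOG2PI = float(np.log(2.0 * np.pi))


@njit(cache=False)
def _logdet_chol(a):
    L = np.linalg.cholesky(a)
    s = 0.0
    for i in range(a.shape[0]):
        s += np.log(L[i, i])
    return 2.0 * s


@njit(cache=False)
def filter_smoother(ys, offset, gamma, var, p0):
    """Returns (loglik, ahat (M, T), vhat (T, M, M))."""
    N, T = ys.shape
    M = gamma.shape[1]
    I = np.eye(M)

    a_pred = np.zeros((T, M))
    P_pred = np.zeros((T, M, M))
    a_filt = np.zeros((T, M))
    P_filt = np.zeros((T, M, M))

    a = np.zeros(M)
    P = p0 * np.eye(M)
    ll = 0.0
    for t in range(T):
        a_p = a
        P_p = P + I
        a_pred[t] = a_p
        P_pred[t] = P_p

        C = np.zeros((M, M))
        u = np.zeros(M)
        quad_r = 0.0
        sumlogvar = 0.0
        n_o = 0
        for i in range(N):
            yit = ys[i, t]
            if np.isnan(yit):
                continue
            n_o += 1
            rinv = 1.0 / var[i]
            g = gamma[i]
            r = yit - offset[i, t] - np.dot(g, a_p)
            for j in range(M):
                u[j] += g[j] * rinv * r
                for k in range(M):
                    C[j, k] += g[j] * g[k] * rinv
            quad_r += r * r * rinv
            sumlogvar += np.log(var[i])

        if n_o > 0:
            Pinv = np.linalg.inv(P_p)
            S = Pinv + C
            P_f = np.linalg.inv(S)
            P_f = 0.5 * (P_f + P_f.T)
            a_f = a_p + P_f @ u
            ll += -0.5 * (
                n_o * _LOG2PI
                + sumlogvar
                + _logdet_chol(P_p)
                + _logdet_chol(S)
                + (quad_r - np.dot(u, P_f @ u))
            )
            a, P = a_f, P_f
        else:
            a, P = a_p, P_p
        a_filt[t] = a
        P_filt[t] = P

    ahat = np.zeros((T, M))
    vhat = np.zeros((T, M, M))
    ahat[T - 1] = a_filt[T - 1]
    vhat[T - 1] = P_filt[T - 1]
    for t in range(T - 2, -1, -1):
        J = P_filt[t] @ np.linalg.inv(P_pred[t + 1])
        ahat[t] = a_filt[t] + J @ (ahat[t + 1] - a_pred[t + 1])
        V = P_filt[t] + J @ (vhat[t + 1] - P_pred[t + 1]) @ J.T
        vhat[t] = 0.5 * (V + V.T)
    return ll, ahat.T.copy(), vhat
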