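"""Memory-lean weighted logistic regression for person-interval models.

Interval tables run to millions of rows; the general-purpose GLM machinery
allocates several design-matrix copies per IRLS iteration, which is wasteful
at that scale.  This Newton solver with step-halving keeps peak memory at
roughly two copies of the design matrix and matches the reference
implementation to numerical precision (asserted in the test suite).
"""
from __future__ import annotations

import numpy as np
from scipy.special import expit

from .errors import EstimationError


def fit_logit(X: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None,
              maxiter: int = 100, tol: float = 1e-8):
    """Weighted logistic MLE: returns (params, mu, converged).

    Newton-Raphson on the weighted log-likelihood with step-halving; a
    diverging likelihood path (separation) surfaces as ``converged=False``
    with the current parameters, so callers can name the offending covariate.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=np.float64)
    n, k = X.shape
    beta = np.zeros(k)
    # intercept warm start when the first column is constant
    if np.all(X[:, 0] == 1.0):
        p0 = np.clip(np.average(y, weights=w), 1e-10, 1 - 1e-10)
        beta[0] = np.log(p0 / (1 - p0))

    def nll(b):
        eta = X @ b
        if not np.all(np.isfinite(eta)):
            return np.inf
        # -sum w*(y*eta - log(1+exp(eta))), stable via logaddexp
        return float(np.sum(w * (np.logaddexp(0.0, eta) - y * eta)))

    f = nll(beta)
    for it in range(1, maxiter + 1):
        mu = expit(X @ beta)
        grad = X.T @ (w * (y - mu))
        Wd = w * mu * (1 - mu)
        H = (X * Wd[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(H, grad, rcond=None)
        if not np.all(np.isfinite(step)):
            raise EstimationError("logistic fit produced non-finite update")
        # step-halving line search
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            fc = nll(cand)
            if fc <= f + 1e-12:
                break
            scale *= 0.5
        else:
            return beta, expit(X @ beta), False
        delta = float(np.max(np.abs(scale * step)))
        beta, f = cand, fc
        if delta < tol:
            return beta, expit(X @ beta), True
    return beta, expit(X @ beta), False
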