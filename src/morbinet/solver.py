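"""L1-penalized logistic regression by iteratively reweighted coordinate descent.

Minimizes

    f(b0, beta) = -(1/n) * Bernoulli log-likelihood + lambda * ||beta||_1

with an unpenalized intercept, via an outer quadratic (IRLS) approximation
and an inner cyclic coordinate descent with soft-thresholding — the
standard path algorithm for penalized GLMs. Predictors are used as given
(binary indicators stay in 0/1 coding, unstandardized), which keeps the
stationarity bound lambda_max directly interpretable.
"""

from __future__ import annotations

import numpy as np


class ConvergenceError(RuntimeError):
    """Raised when coordinate descent fails to converge at a given lambda."""


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def log_likelihood(X: np.ndarray, y: np.ndarray, intercept: float, beta: np.ndarray) -> float:
    """Bernoulli log-likelihood (sum over rows), numerically stable."""
    eta = intercept + X @ beta
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def penalized_objective(
    X: np.ndarray, y: np.ndarray, lam: float, intercept: float, beta: np.ndarray
) -> float:
    """(-1/n) log-likelihood + lambda * ||beta||_1 (intercept unpenalized)."""
    n = len(y)
    return -log_likelihood(X, y, intercept, beta) / n + lam * np.abs(beta).sum()


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest lambda at which the penalized solution is all-zero.

    From the KKT stationarity condition at the intercept-only fit:
    lambda_max = max_j |(1/n) sum_i x_ij (y_i - ybar)|.
    """
    n = len(y)
    return float(np.abs(X.T @ (y - y.mean())).max() / n)


def _soft(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def fit_l1_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    warm: tuple[float, np.ndarray] | None = None,
    tol: float = 1e-7,
    max_outer: int = 200,
    max_inner: int = 1000,
) -> tuple[float, np.ndarray]:
    """Fit one penalized logistic regression.

    Parameters
    ----------
    X : (n, d) design matrix (no intercept column).
    y : (n,) binary response.
    lam : penalty level, >= 0.
    warm : optional (intercept, beta) start, e.g. the previous path solution.
    tol : convergence tolerance on the maximum coefficient change per
        outer iteration.

    Returns
    -------
    (intercept, beta)

    Raises
    ------
    ConvergenceError if the outer loop exhausts ``max_outer`` iterations.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n, d = X.shape
    y = np.asarray(y, dtype=float)
    if warm is not None:
        b0 = float(warm[0])
        beta = np.array(warm[1], dtype=float, copy=True)
    else:
        ybar = min(max(y.mean(), 1e-10), 1 - 1e-10)
        b0 = float(np.log(ybar / (1 - ybar)))
        beta = np.zeros(d)

    cols = [np.ascontiguousarray(X[:, j]) for j in range(d)]
    for _ in range(max_outer):
        eta = b0 + X @ beta
        mu = _sigmoid(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-6)
        z = eta + (y - mu) / w
        sw = w.sum()
        h = np.array([(w * c * c).sum() / n for c in cols])
        r = z - eta  # residual of working response at current coefficients

        b0_old, beta_old = b0, beta.copy()
        # inner CD on the weighted least-squares surrogate
        inner_tol = max(tol * 0.1, 1e-12)
        for _ in range(max_inner):
            delta_max = 0.0
            shift = (w * r).sum() / sw
            if shift != 0.0:
                b0 += shift
                r -= shift
                delta_max = abs(shift)
            for j in range(d):
                if h[j] <= 0:
                    continue
                c = cols[j]
                rho = (w * c) @ r / n + h[j] * beta[j]
                # relative KKT slack keeps coefficients exactly zero at
                # lambda >= lambda_max despite float rounding
                if abs(rho) <= lam * (1.0 + 1e-10):
                    bj = 0.0
                else:
                    bj = _soft(rho, lam) / h[j]
                diff = bj - beta[j]
                if diff != 0.0:
                    r -= c * diff
                    beta[j] = bj
                    delta_max = max(delta_max, abs(diff))
            if delta_max < inner_tol:
                break
        outer_delta = max(abs(b0 - b0_old), np.max(np.abs(beta - beta_old), initial=0.0))
        if outer_delta < tol:
            return b0, beta
    raise ConvergenceError(
        f"coordinate descent did not converge at lambda={lam:.3g} "
        f"within {max_outer} outer iterations"
    )
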