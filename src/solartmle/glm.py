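"""Weighted generalized linear model fits used throughout the pipeline.

The iterated-conditional-expectation regressions inside the TMLE need a
quasi-binomial fit: responses are fractional (previous-step predictions in
[0, 1]) and observations carry inverse-probability weights.  The chained
imputation engine additionally needs the asymptotic covariance of the
coefficients so it can draw from an approximate posterior.  A small ridge
penalty keeps the Newton iterations stable under separation, which is a real
concern at n ~ 121 with a dozen predictors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LogitFit", "LinearFit", "fit_logistic", "fit_linear", "expit", "logit"]

_CLIP = 1e-10


def expit(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _CLIP, 1.0 - _CLIP)
    return np.log(p / (1.0 - p))


def _add_intercept(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


@dataclass
class LogitFit:
    """Quasi-binomial regression fit (logit link).

    ``coef`` includes the intercept as its first element; ``cov`` is the
    inverse expected information (ridge-adjusted), used by the imputation
    engine for posterior draws.
    """

    coef: np.ndarray
    cov: np.ndarray
    converged: bool

    def predict(self, X: np.ndarray) -> np.ndarray:
        return expit(_add_intercept(np.asarray(X, float)) @ self.coef)


@dataclass
class LinearFit:
    coef: np.ndarray
    cov: np.ndarray
    sigma2: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return _add_intercept(np.asarray(X, float)) @ self.coef


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    ridge: float = 1e-6,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> LogitFit:
    """Weighted quasi-binomial MLE by Newton-Raphson (IRLS).

    ``y`` may be fractional in [0, 1].  The ridge penalty is not applied to
    the intercept.  Coefficients are capped at |beta| <= 40 to keep
    separated fits finite without changing any prediction materially.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    Xd = _add_intercept(X)
    p = Xd.shape[1]
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    if np.any(w < 0):
        raise ValueError("negative observation weights")
    pen = np.full(p, ridge)
    pen[0] = 0.0
    beta = np.zeros(p)
    # start the intercept at the weighted-mean logit
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("all observation weights are zero")
    ybar = float(np.clip((w * y).sum() / wsum, 1e-6, 1 - 1e-6))
    beta[0] = np.log(ybar / (1 - ybar))
    converged = False
    for _ in range(max_iter):
        eta = Xd @ beta
        mu = expit(eta)
        v = w * mu * (1.0 - mu)
        grad = Xd.T @ (w * (y - mu)) - pen * beta
        H = (Xd * v[:, None]).T @ Xd + np.diag(pen + 1e-12)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # dampen huge steps (separation)
        mx = np.max(np.abs(step))
        if mx > 10.0:
            step *= 10.0 / mx
        beta = np.clip(beta + step, -40.0, 40.0)
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = Xd @ beta
    mu = expit(eta)
    v = w * mu * (1.0 - mu)
    H = (Xd * v[:, None]).T @ Xd + np.diag(pen + 1e-12)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return LogitFit(coef=beta, cov=cov, converged=converged)


def fit_linear(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    ridge: float = 1e-8,
) -> LinearFit:
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    Xd = _add_intercept(X)
    p = Xd.shape[1]
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    pen = np.full(p, ridge)
    pen[0] = 0.0
    H = (Xd * w[:, None]).T @ Xd + np.diag(pen + 1e-12)
    g = Xd.T @ (w * y)
    try:
        beta = np.linalg.solve(H, g)
        Hinv = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(H, g, rcond=None)[0]
        Hinv = np.linalg.pinv(H)
    resid = y - Xd @ beta
    dof = max(n - p, 1)
    sigma2 = float((w * resid**2).sum() / max(w.sum() * dof / n, 1.0))
    return LinearFit(coef=beta, cov=Hinv * sigma2, sigma2=sigma2)
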