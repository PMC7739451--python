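"""Cross-validated stacking (Super Learner) over a small learner library.

Used as the regression engine for both the treatment mechanism and the
iterated outcome regressions inside the TMLE.  Every learner follows a
minimal contract — ``fit(X, y, weights) -> fitted``, ``fitted.predict(X)`` —
with fractional responses in [0, 1] allowed under the binomial loss, since
ICE regression targets are themselves predicted probabilities.

The ensemble weight vector lives on the probability simplex and minimizes
the cross-validated loss of the convex combination.  The optimum over the
simplex can never be worse than the best single learner (the vertices are
feasible), and the implementation guarantees this numerically by comparing
the optimized combination against every vertex and keeping the best.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import minimize, nnls

from . import glm

logger = logging.getLogger(__name__)

_PCLIP = 1e-6

# ---------------------------------------------------------------------------
# candidate learners
# ---------------------------------------------------------------------------


@dataclass
class _FittedGlm:
    fit: glm.LogitFit | glm.LinearFit
    binary: bool
    expand: "callable"

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.fit.predict(self.expand(np.asarray(X, float)))


class MeanLearner:
    """Intercept-only: predicts the weighted mean response."""

    name = "mean"

    def __init__(self, binary: bool = True):
        self.binary = binary

    def fit(self, X, y, weights=None):
        w = np.ones(len(y)) if weights is None else np.asarray(weights, float)
        mu = float((w * y).sum() / w.sum())

        class _F:
            def predict(_self, Xn):
                return np.full(len(Xn), mu)

        return _F()


class GlmLearner:
    """Main-terms GLM (logistic for binary loss, OLS otherwise)."""

    name = "glm"

    def __init__(self, binary: bool = True, ridge: float = 1e-6):
        self.binary = binary
        self.ridge = ridge

    def _expand(self, X):
        return X

    def fit(self, X, y, weights=None):
        X = self._expand(np.asarray(X, float))
        if self.binary:
            f = glm.fit_logistic(X, np.asarray(y, float), weights, ridge=self.ridge)
        else:
            f = glm.fit_linear(X, np.asarray(y, float), weights, ridge=self.ridge)
        return _FittedGlm(f, self.binary, self._expand)


class InteractionGlmLearner(GlmLearner):
    """GLM with all pairwise interaction terms added."""

    name = "glm_interactions"

    def _expand(self, X):
        X = np.asarray(X, float)
        cols = [X]
        for i, j in combinations(range(X.shape[1]), 2):
            cols.append((X[:, i] * X[:, j])[:, None])
        return np.hstack(cols)


class RidgeGlmLearner(GlmLearner):
    """L2-regularized main-terms GLM (stabilizer for small samples)."""

    name = "glm_ridge"

    def __init__(self, binary: bool = True, ridge: float = 1.0):
        super().__init__(binary=binary, ridge=ridge)


class SaturatedLearner:
    """Nonparametric stratum means over unique covariate patterns.

    Equivalent to a fully interacted GLM at its MLE; patterns unseen during
    fitting fall back to the overall weighted mean.  Intended for all-binary
    covariates.
    """

    name = "saturated"

    def __init__(self, binary: bool = True):
        self.binary = binary

    def fit(self, X, y, weights=None):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        w = np.ones(len(y)) if weights is None else np.asarray(weights, float)
        keys = [tuple(row) for row in X]
        sums: dict[tuple, float] = {}
        wsum: dict[tuple, float] = {}
        for k, yi, wi in zip(keys, y, w):
            sums[k] = sums.get(k, 0.0) + wi * yi
            wsum[k] = wsum.get(k, 0.0) + wi
        table = {k: sums[k] / wsum[k] for k in sums if wsum[k] > 0}
        fallback = float((w * y).sum() / w.sum())

        class _F:
            def predict(_self, Xn):
                Xn = np.asarray(Xn, float)
                return np.array([table.get(tuple(row), fallback) for row in Xn])

        return _F()


def default_library(binary: bool = True) -> "LearnerLibrary":
    """Intercept-only, main-terms GLM, pairwise-interaction GLM, ridge GLM.

    Small, deterministic, and adequate at n ~ 121; extensible through the
    analysis config.
    """
    return LearnerLibrary(
        learners=[
            MeanLearner(binary),
            GlmLearner(binary),
            InteractionGlmLearner(binary),
            RidgeGlmLearner(binary),
        ],
        loss="log" if binary else "squared",
    )


LEARNER_REGISTRY = {
    "mean": MeanLearner,
    "glm": GlmLearner,
    "glm_interactions": InteractionGlmLearner,
    "glm_ridge": RidgeGlmLearner,
    "saturated": SaturatedLearner,
}


def library_from_names(names: list[str], binary: bool = True) -> "LearnerLibrary":
    return LearnerLibrary(
        learners=[LEARNER_REGISTRY[n](binary) for n in names],
        loss="log" if binary else "squared",
    )


# ---------------------------------------------------------------------------
# the stacking ensemble
# ---------------------------------------------------------------------------


@dataclass
class LearnerLibrary:
    learners: list
    loss: str = "log"  # "log" (binary) or "squared" (continuous)

    def __post_init__(self) -> None:
        if not self.learners:
            raise ValueError("library must contain at least one learner")
        if self.loss not in ("log", "squared"):
            raise ValueError(f"unknown loss {self.loss!r}")


def _risk(loss: str, y: np.ndarray, p: np.ndarray, w: np.ndarray) -> float:
    if loss == "log":
        p = np.clip(p, _PCLIP, 1 - _PCLIP)
        return float(-(w * (y * np.log(p) + (1 - y) * np.log(1 - p))).mean())
    return float((w * (y - p) ** 2).mean())


@dataclass
class SuperLearnerFit:
    """Convex combination of candidate learners minimizing CV risk."""

    weights: np.ndarray
    cv_risk: np.ndarray       # per-learner cross-validated risk
    ensemble_cv_risk: float
    folds: int
    seed: int
    loss: str
    fitted: list = field(default_factory=list)   # full-data fits (None if failed)
    n_features: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if X.shape[1] != self.n_features:
            raise ValueError(f"X has {X.shape[1]} columns, expected {self.n_features}")
        out = np.zeros(len(X))
        for a, f in zip(self.weights, self.fitted):
            if a > 0:
                out += a * f.predict(X)
        if self.loss == "log":
            out = np.clip(out, _PCLIP, 1 - _PCLIP)
        return out


def fold_assignment(n: int, V: int, seed: int) -> np.ndarray:
    """Deterministic fold labels in {0..V-1}; depends only on (n, V, seed)."""
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % V
    return labels[rng.permutation(n)]


def fit_super_learner(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    library: LearnerLibrary | None = None,
    V: int | None = None,
    seed: int = 0,
) -> SuperLearnerFit:
    """V-fold cross-validated stacking with simplex weights.

    Weight search: non-negative least squares on the CV prediction matrix
    (renormalized to the simplex) as a starting point, refined by
    simplex-constrained minimization of the declared CV loss, then compared
    against every single-learner vertex; the lowest-risk candidate wins,
    with ties resolved toward earlier learners in the library order.
    A learner that raises during any fold is given weight zero.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    if library is None:
        library = default_library(binary=True)
    if V is None:
        V = 5 if n < 40 else 10
    if n < 2 * V:
        raise ValueError(f"need n >= 2V (n={n}, V={V})")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in X or y")
    w = np.ones(n) if weights is None else np.asarray(weights, float) / np.mean(weights)
    K = len(library.learners)
    folds = fold_assignment(n, V, seed)
    Z = np.zeros((n, K))
    ok = np.ones(K, dtype=bool)
    for k, learner in enumerate(library.learners):
        try:
            for v in range(V):
                tr = folds != v
                te = ~tr
                f = learner.fit(X[tr], y[tr], w[tr])
                Z[te, k] = f.predict(X[te])
        except Exception as e:  # noqa: BLE001 - learner failure gets weight 0
            logger.warning("learner %s failed in cross-validation: %s", getattr(learner, "name", k), e)
            ok[k] = False
    if not ok.any():
        raise RuntimeError("every learner in the library failed")
    if library.loss == "log":
        Z = np.clip(Z, _PCLIP, 1 - _PCLIP)
    cv_risk = np.array(
        [_risk(library.loss, y, Z[:, k], w) if ok[k] else np.inf for k in range(K)]
    )

    # candidate weight vectors, evaluated on the CV risk
    idx = np.flatnonzero(ok)
    Zok = Z[:, idx]
    candidates: list[np.ndarray] = []
    for k in idx:  # vertices first: ties resolve toward earlier learners
        e = np.zeros(K)
        e[k] = 1.0
        candidates.append(e)
    sw = np.sqrt(w)
    coef, _ = nnls(Zok * sw[:, None], y * sw)
    if coef.sum() > 0:
        a = np.zeros(K)
        a[idx] = coef / coef.sum()
        candidates.append(a)
        start = coef / coef.sum()
    else:
        start = np.full(len(idx), 1.0 / len(idx))
    if len(idx) > 1:
        res = minimize(
            lambda a: _risk(library.loss, y, Zok @ a, w),
            start,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * len(idx),
            constraints=[{"type": "eq", "fun": lambda a: a.sum() - 1.0}],
            options={"maxiter": 200, "ftol": 1e-12},
        )
        if res.success or np.isfinite(res.fun):
            a = np.zeros(K)
            aa = np.clip(res.x, 0, None)
            if aa.sum() > 0:
                a[idx] = aa / aa.sum()
                candidates.append(a)
    risks = [_risk(library.loss, y, Z @ a, w) for a in candidates]
    best = int(np.argmin(risks))
    alpha = candidates[best]
    ens_risk = risks[best]

    # zero-weight learners need no full-data refit for prediction
    fitted = [
        learner.fit(X, y, w) if (ok[k] and alpha[k] > 0) else None
        for k, learner in enumerate(library.learners)
    ]
    return SuperLearnerFit(
        weights=alpha,
        cv_risk=cv_risk,
        ensemble_cv_risk=float(ens_risk),
        folds=V,
        seed=seed,
        loss=library.loss,
        fitted=fitted,
        n_features=X.shape[1],
    )


class SuperLearnerEngine:
    """Adapter giving the Super Learner the plain ``fit/predict`` engine contract."""

    def __init__(self, library: LearnerLibrary | None = None, V: int | None = None, seed: int = 0):
        self.library = library
        self.V = V
        self.seed = seed

    def fit(self, X, y, weights=None):
        return fit_super_learner(X, y, weights, self.library, self.V, self.seed)
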