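"""Cross-validated stacking: weights, dominance, reproducibility."""

import numpy as np
import pytest

from solartmle.glm import expit
from solartmle.superlearner import (
    GlmLearner,
    InteractionGlmLearner,
    LearnerLibrary,
    MeanLearner,
    RidgeGlmLearner,
    default_library,
    fit_super_learner,
    fold_assignment,
)


class NoiseLearner:
    """Uninformative deterministic predictions (for weight-recovery tests)."""

    name = "noise"

    def __init__(self, seed=123):
        self.seed = seed

    def fit(self, X, y, weights=None):
        seed = self.seed

        class _F:
            def predict(_self, Xn):
                r = np.random.default_rng(seed)
                return r.uniform(0.1, 0.9, len(Xn))

        return _F()


class FailingLearner:
    name = "failing"

    def fit(self, X, y, weights=None):
        raise RuntimeError("boom")


def _sim_logistic(n, rng):
    X = rng.normal(size=(n, 3))
    p = expit(0.3 + X @ np.array([0.8, -0.5, 0.3]))
    y = (rng.random(n) < p).astype(float)
    return X, y


def test_single_learner_gets_weight_one(rng):
    X, y = _sim_logistic(200, rng)
    fit = fit_super_learner(X, y, library=LearnerLibrary([GlmLearner()], "log"), seed=1)
    assert np.allclose(fit.weights, [1.0])


def test_weights_on_simplex_and_dominance(rng):
    """Ensemble CV risk never exceeds the best single learner's."""
    for rep in range(5):
        X, y = _sim_logistic(300, rng)
        fit = fit_super_learner(X, y, library=default_library(), seed=rep)
        assert np.all(fit.weights >= 0)
        assert np.isclose(fit.weights.sum(), 1.0)
        assert fit.ensemble_cv_risk <= np.min(fit.cv_risk) + 1e-8


def test_true_model_learner_dominates_noise(rng):
    X, y = _sim_logistic(2000, rng)
    lib = LearnerLibrary([GlmLearner(), NoiseLearner()], "log")
    fit = fit_super_learner(X, y, library=lib, seed=3)
    assert fit.weights[0] > 0.8


def test_duplicated_learner_combined_weight(rng):
    X, y = _sim_logistic(500, rng)
    single = fit_super_learner(X, y, library=LearnerLibrary([GlmLearner(), MeanLearner()], "log"), seed=2)
    dup = fit_super_learner(
        X, y, library=LearnerLibrary([GlmLearner(), GlmLearner(), MeanLearner()], "log"), seed=2
    )
    assert dup.weights[0] + dup.weights[1] == pytest.approx(single.weights[0], abs=1e-6)
    Xn = X[:50]
    assert np.allclose(single.predict(Xn), dup.predict(Xn), atol=1e-10)


def test_predict_is_convex_combination(rng):
    X, y = _sim_logistic(400, rng)
    fit = fit_super_learner(X, y, library=default_library(), seed=5)
    preds = np.column_stack(
        [
            (f.predict(X) if f is not None else np.zeros(len(X)))
            for f in fit.fitted
        ]
    )
    active = fit.weights > 0
    lo = preds[:, active].min(axis=1)
    hi = preds[:, active].max(axis=1)
    p = fit.predict(X)
    assert np.all(p >= lo - 1e-9) and np.all(p <= hi + 1e-9)


def test_constant_learners_predict_constant(rng):
    X, y = _sim_logistic(100, rng)
    fit = fit_super_learner(X, y, library=LearnerLibrary([MeanLearner()], "log"), seed=0)
    assert np.allclose(fit.predict(X), y.mean(), atol=1e-12)


def test_fold_assignment_deterministic():
    a = fold_assignment(101, 10, 7)
    b = fold_assignment(101, 10, 7)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, fold_assignment(101, 10, 8))
    assert set(a) == set(range(10))


def test_rerun_reproducibility(rng):
    X, y = _sim_logistic(300, rng)
    f1 = fit_super_learner(X, y, library=default_library(), seed=11)
    f2 = fit_super_learner(X, y, library=default_library(), seed=11)
    assert np.array_equal(f1.weights, f2.weights)
    assert np.allclose(f1.predict(X), f2.predict(X))


def test_weight_scale_invariance(rng):
    X, y = _sim_logistic(300, rng)
    w = rng.uniform(0.5, 2.0, len(y))
    f1 = fit_super_learner(X, y, weights=w, library=default_library(), seed=4)
    f2 = fit_super_learner(X, y, weights=7.3 * w, library=default_library(), seed=4)
    assert np.allclose(f1.weights, f2.weights, atol=1e-10)
    assert np.allclose(f1.predict(X), f2.predict(X), atol=1e-10)


def test_failing_learner_gets_zero_weight(rng):
    X, y = _sim_logistic(200, rng)
    lib = LearnerLibrary([FailingLearner(), GlmLearner()], "log")
    fit = fit_super_learner(X, y, library=lib, seed=6)
    assert fit.weights[0] == 0.0
    assert fit.weights[1] == pytest.approx(1.0)
    with pytest.raises(RuntimeError, match="every learner"):
        fit_super_learner(X, y, library=LearnerLibrary([FailingLearner()], "log"), seed=6)


def test_interaction_learner_expands_features(rng):
    X, y = _sim_logistic(400, rng)
    lib = LearnerLibrary([InteractionGlmLearner(), RidgeGlmLearner()], "log")
    fit = fit_super_learner(X, y, library=lib, seed=9)
    assert np.isclose(fit.weights.sum(), 1.0)
    p = fit.predict(X)
    assert np.all((p > 0) & (p < 1))


def test_requires_enough_rows():
    with pytest.raises(ValueError, match="n >= 2V"):
        fit_super_learner(np.zeros((8, 2)), np.zeros(8), V=5)
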