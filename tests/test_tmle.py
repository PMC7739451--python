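"""The longitudinal TMLE, its targeting step, and the testing comparators."""

import numpy as np
import pandas as pd
import pytest

from solartmle.cohort import CohortTable
from solartmle.nodes import NodeSpec
from solartmle.superlearner import GlmLearner, MeanLearner, SaturatedLearner
from solartmle.synthetic import (
    Equation,
    StructuralModel,
    counterfactual_truth,
    simulate,
    small_binary_model,
)
from solartmle.tmle import (
    Regime,
    fit_treatment_mechanism,
    gformula_oracle,
    iptw_comparator,
    scale_continuous_outcome,
    tmle_counterfactual_mean,
)

from conftest import toy_table


@pytest.fixture(scope="module")
def saturated_setup(big_binary_cohort):
    g = fit_treatment_mechanism(big_binary_cohort, SaturatedLearner(), truncation=(0.001, 0.999))
    return big_binary_cohort, g


# -- treatment mechanism ----------------------------------------------------


def test_randomized_treatment_recovers_half(rng):
    """With A ~ Bernoulli(0.5) independent of history, g-hat ~ 0.5."""
    model = small_binary_model()
    eqs = dict(model.equations)
    eqs["A1"] = Equation(0.0, {}, clip=(0.05, 0.95))
    eqs["A2"] = Equation(0.0, {}, clip=(0.05, 0.95))
    rand = StructuralModel(model.node_specs, eqs, seed=1)
    tab = simulate(rand, 8000, seed=2, missingness=False)
    g = fit_treatment_mechanism(tab, GlmLearner())
    for name in ("A1", "A2"):
        p = g.prob(name, tab)
        assert np.all(np.abs(p - 0.5) < 0.05)


def test_truncation_clips_predictions(saturated_setup):
    tab, _ = saturated_setup
    g = fit_treatment_mechanism(tab, GlmLearner(), truncation=(0.45, 0.55))
    p = g.prob("A1", tab)
    assert p.min() >= 0.45 and p.max() <= 0.55


def test_cumulative_g_is_product(saturated_setup):
    tab, g = saturated_setup
    r = Regime((1, 1))
    g1 = g.prob("A1", tab)
    g2 = g.prob("A2", tab)
    assert np.allclose(g.cumulative_g(tab, r), g1 * g2, atol=1e-12)
    r0 = Regime((0, 1))
    assert np.allclose(g.cumulative_g(tab, r0), (1 - g1) * g2, atol=1e-12)


def test_degenerate_treatment_errors():
    rows = [dict(W=0, L1=0, A1=1, Y1=0, L2=0, A2=0, Y2=0) for _ in range(30)]
    with pytest.raises(ValueError, match="A1"):
        fit_treatment_mechanism(toy_table(rows), GlmLearner())


# -- the estimator ----------------------------------------------------------


def test_observed_regime_is_empirical_mean(saturated_setup):
    tab, _ = saturated_setup
    fit = tmle_counterfactual_mean(tab, Regime("observed"), 3)
    assert fit.psi == pytest.approx(float(tab.df["Y3"].mean()), abs=1e-15)
    assert abs(fit.ic.mean()) < 1e-10


def test_saturated_tmle_equals_gformula_and_iptw(saturated_setup):
    """Nonparametric Q and g collapse the TMLE onto the plug-in g-formula."""
    tab, g = saturated_setup
    for reg in [(0, 0), (1, 1)]:
        r = Regime(reg)
        fit = tmle_counterfactual_mean(tab, r, 3, SaturatedLearner(), g)
        assert abs(fit.psi - gformula_oracle(tab, r, 3)) < 1e-8
        assert abs(iptw_comparator(tab, r, 3, g) - fit.psi) <= 3 * fit.se


def test_influence_curve_mean_zero(saturated_setup):
    tab, g = saturated_setup
    for reg in [(0, 0), (1, 0), (1, 1)]:
        fit = tmle_counterfactual_mean(tab, Regime(reg), 3, GlmLearner(), g)
        assert abs(fit.ic.mean()) < 1e-8
        assert fit.se >= 0


def test_wave2_uses_both_treatments(saturated_setup):
    tab, g = saturated_setup
    fit = tmle_counterfactual_mean(tab, Regime((1, 1)), 2, SaturatedLearner(), g)
    assert abs(fit.psi - gformula_oracle(tab, Regime((1, 1)), 2)) < 1e-8
    assert len(fit.epsilons) == 2


def test_psi_invariant_to_subject_permutation(saturated_setup, rng):
    tab, _ = saturated_setup
    sub = CohortTable(tab.df.head(4000).copy(), tab.node_specs)
    perm_df = sub.df.iloc[rng.permutation(sub.n)].reset_index(drop=True)
    perm = CohortTable(perm_df, tab.node_specs)
    g1 = fit_treatment_mechanism(sub, SaturatedLearner())
    g2 = fit_treatment_mechanism(perm, SaturatedLearner())
    f1 = tmle_counterfactual_mean(sub, Regime((1, 1)), 3, SaturatedLearner(), g1)
    f2 = tmle_counterfactual_mean(perm, Regime((1, 1)), 3, SaturatedLearner(), g2)
    assert f1.psi == pytest.approx(f2.psi, abs=1e-10)
    assert np.sort(f1.ic) == pytest.approx(np.sort(f2.ic), abs=1e-8)


def test_missing_data_rejected(solar_cohort):
    g_err = pytest.raises(ValueError, match="impute")
    with g_err:
        fit_treatment_mechanism(solar_cohort, GlmLearner())


def test_zero_followers_raises():
    rows = [dict(W=0, L1=0, A1=0, Y1=0, L2=0, A2=0, Y2=0) for _ in range(30)]
    rows += [dict(W=1, L1=1, A1=1, Y1=1, L2=1, A2=0, Y2=1) for _ in range(30)]
    rows += [dict(W=1, L1=0, A1=0, Y1=1, L2=1, A2=1, Y2=0) for _ in range(30)]
    tab = toy_table(rows)
    g = fit_treatment_mechanism(tab, MeanLearner())
    with pytest.raises(ValueError, match="positivity"):
        tmle_counterfactual_mean(tab, Regime((1, 1)), 2, GlmLearner(), g)


def test_randomized_design_recovers_truth():
    """Randomized treatments + correct Q: psi unbiased over replicates."""
    model = small_binary_model()
    eqs = dict(model.equations)
    eqs["A1"] = Equation(0.0, {}, clip=(0.05, 0.95))
    eqs["A2"] = Equation(0.0, {}, clip=(0.05, 0.95))
    rand = StructuralModel(model.node_specs, eqs, seed=1)
    truth = gformula_oracle(rand, Regime((1, 1)), 3)
    psis = []
    for rep in range(40):
        tab = simulate(rand, 800, seed=100 + rep, missingness=False)
        g = fit_treatment_mechanism(tab, GlmLearner())
        fit = tmle_counterfactual_mean(tab, Regime((1, 1)), 3, GlmLearner(), g)
        psis.append(fit.psi)
    mc_se = np.std(psis, ddof=1) / np.sqrt(len(psis))
    assert abs(np.mean(psis) - truth) < 3 * mc_se


# -- oracle and IPTW --------------------------------------------------------


def test_oracle_hand_computation_single_confounder():
    """P(L=1)=0.5, P(Y|L0,A1)=0.2, P(Y|L1,A1)=0.6 -> psi(A=1) = 0.4."""
    specs = [
        NodeSpec("L1", "confounder", 1),
        NodeSpec("A1", "treatment", 1),
        NodeSpec("Y1", "outcome", 1),
    ]
    rows = []
    # saturated empirical table realizing exactly those frequencies
    for L in (0, 1):
        for A in (0, 1):
            py = {(0, 1): 0.2, (1, 1): 0.6, (0, 0): 0.3, (1, 0): 0.5}[(L, A)]
            for i in range(10):
                rows.append(dict(L1=L, A1=A, Y1=float(i < 10 * py)))
    tab = CohortTable(pd.DataFrame(rows, dtype=float), specs)
    psi = gformula_oracle(tab, Regime((1,)), 1)
    assert psi == pytest.approx(0.5 * 0.2 + 0.5 * 0.6)


def test_oracle_no_confounding():
    specs = [
        NodeSpec("A1", "treatment", 1),
        NodeSpec("Y1", "outcome", 1),
    ]
    rows = [dict(A1=1, Y1=float(i < 7)) for i in range(10)]
    rows += [dict(A1=0, Y1=float(i < 2)) for i in range(10)]
    tab = CohortTable(pd.DataFrame(rows, dtype=float), specs)
    assert gformula_oracle(tab, Regime((1,)), 1) == pytest.approx(0.7)


def test_oracle_invariant_to_row_order(big_binary_cohort, rng):
    tab = big_binary_cohort
    perm = CohortTable(tab.df.iloc[rng.permutation(tab.n)].reset_index(drop=True), tab.node_specs)
    a = gformula_oracle(tab, Regime((1, 0)), 3)
    b = gformula_oracle(perm, Regime((1, 0)), 3)
    assert a == pytest.approx(b, abs=1e-12)


def test_iptw_all_followers_gives_mean():
    rows = [dict(W=0, L1=0, A1=1, Y1=i % 2, L2=0, A2=1, Y2=(i // 2) % 2) for i in range(20)]
    tab = toy_table(rows)
    specs = tab.node_specs

    class ConstantG:
        nodes = [s for s in specs if s.role == "treatment"]
        truncation = (0.001, 0.999)

        def prob(self, name, table):
            return np.ones(table.n)  # truncated to 0.999 below

        def cumulative_g(self, table, regime, through=None):
            return np.ones(table.n)

    psi = iptw_comparator(tab, Regime((1, 1)), 2, ConstantG())
    assert psi == pytest.approx(float(tab.df["Y2"].mean()))


def test_iptw_randomized_matches_follower_mean():
    model = small_binary_model()
    eqs = dict(model.equations)
    eqs["A1"] = Equation(0.0, {}, clip=(0.05, 0.95))
    eqs["A2"] = Equation(0.0, {}, clip=(0.05, 0.95))
    rand = StructuralModel(model.node_specs, eqs, seed=1)
    tab = simulate(rand, 30_000, seed=77, missingness=False)
    g = fit_treatment_mechanism(tab, MeanLearner())
    follow = (tab.df["A1"] == 1) & (tab.df["A2"] == 1)
    strat = float(tab.df.loc[follow, "Y3"].mean())
    psi = iptw_comparator(tab, Regime((1, 1)), 3, g)
    assert psi == pytest.approx(strat, abs=0.02)


# -- continuous outcome scaling --------------------------------------------


def test_scale_continuous_outcome_roundtrip(rng):
    y = rng.uniform(60, 95, 200)
    s, (lo, hi) = scale_continuous_outcome(y)
    assert s.min() == 0.0 and s.max() == 1.0
    assert np.allclose(lo + s * (hi - lo), y)
    s2, _ = scale_continuous_outcome(np.array([75.0]), (0.0, 100.0))
    assert s2[0] == 0.75
    with pytest.raises(ValueError, match="constant"):
        scale_continuous_outcome(np.full(5, 3.0))


def test_continuous_outcome_tmle(solar_model):
    tab = simulate(solar_model, 2000, seed=55, missingness=False)
    g = fit_treatment_mechanism(tab, GlmLearner())
    f1 = tmle_counterfactual_mean(tab, Regime((1, 1)), 3, GlmLearner(), g, outcome="lfr3")
    f0 = tmle_counterfactual_mean(tab, Regime((0, 0)), 3, GlmLearner(), g, outcome="lfr3")
    lo, hi = f1.outcome_scale
    assert lo <= f1.psi <= hi
    # harmful lung-function effect: sustained treatment lowers the ratio
    assert f1.psi < f0.psi
    assert abs(f1.ic.mean()) < 1e-8 * (hi - lo)
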