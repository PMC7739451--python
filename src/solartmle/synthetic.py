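"""Synthetic longitudinal asthma cohorts with known counterfactual truth.

The generator draws subjects from explicit structural equations in the
temporal ordering W, L1, A1, Y1, L2, A2, Y2, L3, Y3 and then (optionally)
masks values through MAR missingness models, so every downstream stage —
imputation, Super Learner, TMLE — can be tested against exact ground truth
obtained by re-running the same equations under an intervention.

The default parameterization emulates a panel of ~121 asthmatic children
followed over three questionnaire waves: high early symptom prevalence that
settles to about two thirds, control-medication use that falls from roughly
55% to 15% across the first two waves, and confounding by a latent binary
disease *severity* that raises both the probability of taking control
medication and the probability of reporting symptoms.  Severity is emitted
as a column so analyses can choose to adjust for it (identifiable setting)
or drop it (the reverse-causation structure suspected in real cohorts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .glm import expit
from .nodes import NodeSpec, treatment_nodes

OBSERVED = "observed"

# treatment propensities are kept inside these bounds by construction, so
# positivity holds in every generated cohort
POSITIVITY_BOUNDS = (0.05, 0.95)


@dataclass(frozen=True)
class Equation:
    """One structural equation: linear predictor over named parents.

    ``kind`` "logistic" yields a Bernoulli draw with probability
    expit(intercept + coeffs·parents); "linear" yields a Gaussian draw with
    that mean and ``sigma``.  ``gate`` names a binary parent that forces the
    node to 0 when the parent is 1 (used for "reliever only" indicators,
    which are structurally impossible under control-medication use).
    ``clip`` bounds the success probability (used for treatment nodes).
    """

    intercept: float
    coeffs: dict[str, float] = field(default_factory=dict)
    kind: str = "logistic"
    sigma: float = 0.0
    gate: str | None = None
    clip: tuple[float, float] | None = None

    def linpred(self, columns: dict[str, np.ndarray]) -> np.ndarray:
        n = len(next(iter(columns.values()))) if columns else 1
        eta = np.full(n, self.intercept, dtype=float)
        for name, c in self.coeffs.items():
            eta = eta + c * columns[name]
        return eta

    def prob(self, columns: dict[str, np.ndarray]) -> np.ndarray:
        if self.kind != "logistic":
            raise ValueError("prob() only defined for logistic equations")
        p = expit(self.linpred(columns))
        if self.clip is not None:
            p = np.clip(p, *self.clip)
        if self.gate is not None:
            p = p * (1.0 - columns[self.gate])
        return p


@dataclass
class StructuralModel:
    """A full data-generating process for the longitudinal cohort.

    ``node_specs`` gives the emitted columns in temporal order;
    ``equations`` maps every node name to its structural equation;
    ``missingness`` maps node names to MAR logistic models for the
    *missingness indicator* given always-observed nodes; ``effect_size``
    records the treatment log-odds coefficients for reference.
    """

    node_specs: list[NodeSpec]
    equations: dict[str, Equation]
    missingness: dict[str, Equation] = field(default_factory=dict)
    effect_size: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for s in self.node_specs:
            if s.name not in self.equations:
                raise ValueError(f"no structural equation for node {s.name!r}")
            eq = self.equations[s.name]
            bad = [c for c in eq.coeffs if not np.isfinite(eq.coeffs[c])]
            if bad or not np.isfinite(eq.intercept):
                raise ValueError(f"non-finite coefficient in equation for {s.name!r}")

    def treatment_names(self) -> list[str]:
        return [s.name for s in treatment_nodes(self.node_specs)]


@dataclass(frozen=True)
class TruthRecord:
    """Monte-Carlo counterfactual risk for one regime at one wave."""

    regime: tuple[int, ...] | str
    wave: int
    risk: float
    mc_reps: int
    mc_se: float


def _draw_nodes(
    model: StructuralModel,
    n: int,
    rng: np.random.Generator,
    intervention: dict[str, int] | None = None,
) -> dict[str, np.ndarray]:
    intervention = intervention or {}
    cols: dict[str, np.ndarray] = {}
    for spec in model.node_specs:
        eq = model.equations[spec.name]
        if spec.name in intervention:
            cols[spec.name] = np.full(n, float(intervention[spec.name]))
        elif eq.kind == "logistic":
            p = eq.prob(cols)
            cols[spec.name] = (rng.random(n) < p).astype(float)
        elif eq.kind == "linear":
            cols[spec.name] = eq.linpred(cols) + rng.normal(0.0, eq.sigma, n)
        else:
            raise ValueError(f"unknown equation kind {eq.kind!r}")
    return cols


def simulate(
    model: StructuralModel,
    n: int,
    seed: int | None = None,
    missingness: bool = True,
) -> CohortTable:
    """Draw a cohort of ``n`` subjects; reproducible from the seed.

    Complete data are drawn first in temporal order, then masked by the MAR
    missingness models (whose predictors are restricted to always-observed
    nodes, so missingness never depends on an unobserved value).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    cols = _draw_nodes(model, n, rng)
    df = pd.DataFrame({s.name: cols[s.name] for s in model.node_specs})
    if missingness:
        for name, eq in model.missingness.items():
            p_miss = expit(eq.linpred(cols))
            mask = rng.random(n) < p_miss
            df.loc[mask, name] = np.nan
    return CohortTable(df, list(model.node_specs))


def treatment_propensities(model: StructuralModel, n: int, seed: int | None = None) -> dict[str, np.ndarray]:
    """The generator's own treatment probabilities along a simulated cohort."""
    rng = np.random.default_rng(model.seed if seed is None else seed)
    cols = _draw_nodes(model, n, rng)
    return {name: model.equations[name].prob(cols) for name in model.treatment_names()}


def counterfactual_truth(
    model: StructuralModel,
    regime: tuple[int, ...] | str,
    wave: int,
    mc_reps: int = 100_000,
    seed: int | None = None,
    outcome: str | None = None,
) -> TruthRecord:
    """Interventional Monte-Carlo mean of the wave-``wave`` outcome.

    For a static regime (a1, a2) the treatment nodes are fixed by
    intervention (missingness is never applied — this is the full-data
    truth); for the sentinel "observed" the natural treatment equations run.
    ``outcome`` defaults to the binary symptom node at the wave.
    """
    rng = np.random.default_rng((model.seed if seed is None else seed) + 1)
    intervention: dict[str, int] | None = None
    if regime != OBSERVED:
        tnames = model.treatment_names()
        if len(regime) != len(tnames):
            raise ValueError(f"regime length {len(regime)} != {len(tnames)} treatment nodes")
        intervention = {name: int(a) for name, a in zip(tnames, regime)}
    if outcome is None:
        cands = [s.name for s in model.node_specs if s.role == "outcome" and s.wave == wave and s.value_kind == "binary"]
        if not cands:
            raise ValueError(f"no binary outcome node at wave {wave}")
        outcome = cands[0]
    cols = _draw_nodes(model, mc_reps, rng, intervention)
    y = cols[outcome]
    risk = float(np.mean(y))
    mc_se = float(np.std(y, ddof=1) / np.sqrt(mc_reps))
    return TruthRecord(regime=regime, wave=wave, risk=risk, mc_reps=mc_reps, mc_se=mc_se)


def drop_columns(table: CohortTable, names: list[str]) -> CohortTable:
    """Return the table without the named columns (e.g. the latent severity)."""
    keep = [s for s in table.node_specs if s.name not in names]
    return CohortTable(table.df[[s.name for s in keep]].copy(), keep)


def widen_exposure(table: CohortTable, pairs: list[tuple[str, str]] | None = None) -> CohortTable:
    """Recode each treatment node as control OR reliever medication.

    ``pairs`` maps treatment node -> reliever-use node; the reliever node is
    dropped after recoding.  Missing in either component propagates.
    """
    if pairs is None:
        pairs = [("A1", "rel1"), ("A2", "rel2")]
    df = table.df.copy()
    dropped = []
    for a, r in pairs:
        df[a] = np.fmax(df[a], df[r]).where(~(df[a].isna() | df[r].isna()), np.nan)
        dropped.append(r)
    keep = [s for s in table.node_specs if s.name not in dropped]
    return CohortTable(df[[s.name for s in keep]], keep)


# ---------------------------------------------------------------------------
# packaged parameterizations
# ---------------------------------------------------------------------------


def default_solar_model(
    effect_a1: float = 0.30,
    effect_a2: float = 0.60,
    lf_effect_a1: float = -1.8,
    lf_effect_a2: float = -2.7,
    seed: int = 20260301,
) -> StructuralModel:
    """The packaged SOLAR-like cohort model.

    Intercepts are calibrated so that large-n marginals approximate the
    observed cohort: symptom prevalence ~0.96 / 0.66 / 0.65 by wave,
    control-medication use ~0.55 at wave 1 and ~0.15 at wave 2,
    reliever-only use ~0.16 / 0.25, hay fever ~0.26-0.31, and per-node
    missingness between ~1% and ~10%.  ``effect_a1``/``effect_a2`` are the
    log-odds of wave-1/wave-2 control medication on later symptoms
    (positive = harmful, as the reverse-causation structure suggests);
    ``lf_effect_a1``/``lf_effect_a2`` are additive effects on the continuous
    FEV1s/FVC (%) lung-function outcome.
    """
    specs = [
        NodeSpec("sex", "baseline", 1),
        NodeSpec("ses", "baseline", 1),
        NodeSpec("centre", "baseline", 1),
        NodeSpec("par_asthma", "baseline", 1),
        NodeSpec("severity", "baseline", 1),
        NodeSpec("hayfever1", "confounder", 1),
        NodeSpec("A1", "treatment", 1),
        NodeSpec("Y1", "outcome", 1),
        NodeSpec("hayfever2", "confounder", 2),
        NodeSpec("rel1", "confounder", 2),
        NodeSpec("A2", "treatment", 2),
        NodeSpec("Y2", "outcome", 2),
        NodeSpec("hayfever3", "confounder", 3),
        NodeSpec("rel2", "confounder", 3),
        NodeSpec("Y3", "outcome", 3),
        NodeSpec("lfr3", "outcome", 3, "continuous"),
    ]
    clip = POSITIVITY_BOUNDS
    eqs = {
        "sex": Equation(0.668),       # P ~ 0.661 male
        "ses": Equation(0.084),       # P ~ 0.521 high SES
        "centre": Equation(0.250),    # P ~ 0.562 Munich
        "par_asthma": Equation(-1.343),  # P ~ 0.207
        "severity": Equation(-0.405),    # P ~ 0.400 latent severe phenotype
        "hayfever1": Equation(-1.341, {"par_asthma": 0.45, "severity": 0.35, "sex": 0.10}),
        "A1": Equation(-0.420, {"severity": 0.90, "hayfever1": 0.50, "par_asthma": 0.30, "ses": 0.20}, clip=clip),
        "Y1": Equation(2.510, {"severity": 1.40, "hayfever1": 0.60, "A1": effect_a1}),
        "hayfever2": Equation(-1.314, {"hayfever1": 1.30, "severity": 0.25}),
        "rel1": Equation(-0.787, {"severity": 0.40, "hayfever1": 0.30}, gate="A1"),
        "A2": Equation(-3.289, {"A1": 1.10, "severity": 0.80, "hayfever2": 0.40, "Y1": 0.30}, clip=clip),
        "Y2": Equation(-0.711, {"severity": 1.10, "hayfever2": 0.50, "Y1": 0.70, "A1": effect_a1 * 0.8, "A2": effect_a2 * 0.8}),
        "hayfever3": Equation(-1.554, {"hayfever2": 1.30, "severity": 0.25}),
        "rel2": Equation(-1.286, {"rel1": 0.80, "severity": 0.30, "Y2": 0.20}, gate="A2"),
        "Y3": Equation(-0.611, {"severity": 1.10, "hayfever3": 0.50, "Y2": 0.80, "A1": effect_a1, "A2": effect_a2}),
        "lfr3": Equation(
            88.0,
            {"severity": -3.0, "Y2": -1.0, "hayfever3": -1.5, "sex": 0.5, "A1": lf_effect_a1, "A2": lf_effect_a2},
            kind="linear",
            sigma=5.0,
        ),
    }
    # MAR missingness: predictors restricted to always-observed nodes
    def miss(rate_logit: float) -> Equation:
        return Equation(rate_logit, {"sex": 0.30, "centre": -0.30})

    missingness = {
        "ses": miss(-4.80),        # ~0.8%
        "par_asthma": miss(-2.168), # ~10.7%
        "hayfever1": miss(-3.89),  # ~2%
        "A1": miss(-2.348),         # ~9.1%
        "rel1": miss(-2.348),       # same instrument as A1
        "hayfever2": miss(-4.18),  # ~1.5%
        "A2": miss(-3.427),         # ~3.3%
        "rel2": miss(-3.427),
        "Y2": miss(-4.06),         # ~1.7%
        "hayfever3": miss(-4.18),
        "Y3": miss(-4.80),         # ~0.8%
        "lfr3": miss(-2.243),       # spirometry subsample, ~10%
    }
    return StructuralModel(
        node_specs=specs,
        equations=eqs,
        missingness=missingness,
        effect_size={"A1": effect_a1, "A2": effect_a2, "lfr3_A1": lf_effect_a1, "lfr3_A2": lf_effect_a2},
        seed=seed,
    )


def small_binary_model(seed: int = 7) -> StructuralModel:
    """An all-binary model (one baseline, one confounder per wave).

    Every conditional probability stays well inside (0.2, 0.8), so all
    covariate-treatment strata are populated at moderate n — the setting in
    which the saturated-regression TMLE, the exhaustive g-formula plug-in
    and IPTW must agree.
    """
    specs = [
        NodeSpec("W", "baseline", 1),
        NodeSpec("L1", "confounder", 1),
        NodeSpec("A1", "treatment", 1),
        NodeSpec("Y1", "outcome", 1),
        NodeSpec("L2", "confounder", 2),
        NodeSpec("A2", "treatment", 2),
        NodeSpec("Y2", "outcome", 2),
        NodeSpec("L3", "confounder", 3),
        NodeSpec("Y3", "outcome", 3),
    ]
    clip = POSITIVITY_BOUNDS
    eqs = {
        "W": Equation(0.0),
        "L1": Equation(-0.2, {"W": 0.5}),
        "A1": Equation(-0.3, {"W": 0.4, "L1": 0.5}, clip=clip),
        "Y1": Equation(-0.4, {"W": 0.3, "L1": 0.5, "A1": 0.4}),
        "L2": Equation(-0.3, {"L1": 0.5, "A1": 0.3, "Y1": 0.3}),
        "A2": Equation(-0.5, {"W": 0.3, "L2": 0.4, "A1": 0.6, "Y1": 0.3}, clip=clip),
        "Y2": Equation(-0.5, {"W": 0.3, "L2": 0.4, "A1": 0.3, "A2": 0.5, "Y1": 0.4}),
        "L3": Equation(-0.3, {"L2": 0.5, "A2": 0.3, "Y2": 0.3}),
        "Y3": Equation(-0.6, {"W": 0.3, "L3": 0.4, "A1": 0.3, "A2": 0.5, "Y2": 0.5}),
    }
    return StructuralModel(
        node_specs=specs,
        equations=eqs,
        missingness={},
        effect_size={"A1": 0.3, "A2": 0.5},
        seed=seed,
    )


def with_null_effect(model: StructuralModel) -> StructuralModel:
    """Copy of the model with every treatment coefficient on outcomes set to 0."""
    tnames = set(model.treatment_names())
    eqs = {}
    for spec in model.node_specs:
        eq = model.equations[spec.name]
        if spec.role == "outcome":
            coeffs = {k: (0.0 if k in tnames else v) for k, v in eq.coeffs.items()}
            eq = replace(eq, coeffs=coeffs)
        eqs[spec.name] = eq
    return StructuralModel(
        node_specs=list(model.node_specs),
        equations=eqs,
        missingness=dict(model.missingness),
        effect_size={k: 0.0 for k in model.effect_size},
        seed=model.seed,
    )
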