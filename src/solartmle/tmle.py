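"""Longitudinal TMLE of counterfactual outcome means under static regimes.

The estimator is the iterated-conditional-expectation (ICE) form: starting
from the outcome at the queried wave, outcome regressions are taken
backwards through the treatment nodes, and each regression is *targeted* by
a weighted intercept-only logistic fluctuation whose weights are the
regime-follower indicator divided by the cumulative (truncated) treatment
probability.  The final targeted prediction, averaged over subjects, is the
counterfactual mean psi; the per-subject influence curve is the telescoping
sum of weighted residuals plus the centred final prediction, and its sample
variance over n gives the standard error.

A brute-force g-formula plug-in by exhaustive enumeration and a
Horvitz-Thompson IPTW mean are provided as independent comparators for
testing; they are never part of the estimator itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortTable
from .glm import expit, logit
from .nodes import NodeSpec, history_names
from .synthetic import StructuralModel

logger = logging.getLogger(__name__)

OBSERVED = "observed"
_QCLIP = 1e-6


@dataclass(frozen=True)
class Regime:
    """A static assignment to the treatment nodes, or the sentinel "observed"."""

    assignments: tuple[int, ...] | str

    def __post_init__(self) -> None:
        a = self.assignments
        if a == OBSERVED:
            return
        if not isinstance(a, tuple) or not all(v in (0, 1) for v in a):
            raise ValueError(f"regime must be a 0/1 tuple or 'observed', got {a!r}")

    @property
    def is_observed(self) -> bool:
        return self.assignments == OBSERVED

    def label(self) -> str:
        if self.is_observed:
            return OBSERVED
        return "(" + ",".join(str(v) for v in self.assignments) + ")"


def _require_complete(table: CohortTable, names: list[str]) -> None:
    sub = table.df[names]
    if sub.isna().to_numpy().any():
        bad = [c for c in names if sub[c].isna().any()]
        raise ValueError(f"missing values in column(s) {bad}; impute before estimation")


# ---------------------------------------------------------------------------
# treatment mechanism
# ---------------------------------------------------------------------------


@dataclass
class TreatmentMechanism:
    """Fitted P(A_t = 1 | past) per treatment node, with truncation bounds."""

    nodes: list[NodeSpec]
    histories: dict[str, list[str]]
    fits: dict[str, object]
    truncation: tuple[float, float]
    diagnostics: dict[str, dict] = field(default_factory=dict)

    def prob(self, name: str, table: CohortTable) -> np.ndarray:
        """Truncated predicted probability of A=1 at node ``name``."""
        X = table.df[self.histories[name]].to_numpy(dtype=float)
        p = np.asarray(self.fits[name].predict(X), float)
        return np.clip(p, *self.truncation)

    def cumulative_g(
        self, table: CohortTable, regime: Regime, through: int | None = None
    ) -> np.ndarray:
        """Product over treatment nodes of P(A_s = a_s | past), truncated.

        ``through`` limits the product to the first ``through``+1 nodes.
        """
        a = regime.assignments
        out = np.ones(table.n)
        upto = len(self.nodes) if through is None else through + 1
        for s, node in enumerate(self.nodes[:upto]):
            g1 = self.prob(node.name, table)
            out *= np.where(a[s] == 1, g1, 1.0 - g1)
        return out


def fit_treatment_mechanism(
    table: CohortTable,
    engine,
    truncation: tuple[float, float] = (0.01, 0.99),
    waves: tuple[int, ...] = (1, 2),
) -> TreatmentMechanism:
    """Fit the treatment-assignment models on complete (post-imputation) data.

    ``engine`` follows the ``fit(X, y, weights) -> fitted`` contract (a
    learner or a :class:`~solartmle.superlearner.SuperLearnerEngine`).
    Positivity diagnostics — min/max predicted probability and the count of
    predictions outside the truncation bounds — are logged and stored.
    """
    lo, hi = truncation
    if not (0 < lo < hi < 1):
        raise ValueError("truncation bounds must satisfy 0 < lower < upper < 1")
    tnodes = [s for s in table.node_specs if s.role == "treatment" and s.wave in waves]
    if not tnodes:
        raise ValueError("no treatment nodes in table")
    fits: dict[str, object] = {}
    hists: dict[str, list[str]] = {}
    diags: dict[str, dict] = {}
    for node in tnodes:
        hist = history_names(table.node_specs, node)
        _require_complete(table, hist + [node.name])
        y = table.values(node.name)
        if y.min() == y.max():
            raise ValueError(f"degenerate treatment node {node.name!r}: all values are {y[0]:.0f}")
        X = table.df[hist].to_numpy(dtype=float)
        f = engine.fit(X, y)
        raw = np.asarray(f.predict(X), float)
        diags[node.name] = {
            "min_pred": float(raw.min()),
            "max_pred": float(raw.max()),
            "n_below_lower": int((raw < lo).sum()),
            "n_above_upper": int((raw > hi).sum()),
        }
        logger.info(
            "g fit %s: predicted range [%.4f, %.4f], %d below %.2g",
            node.name, raw.min(), raw.max(), diags[node.name]["n_below_lower"], lo,
        )
        fits[node.name] = f
        hists[node.name] = hist
    return TreatmentMechanism(
        nodes=tnodes, histories=hists, fits=fits, truncation=truncation, diagnostics=diags
    )


# ---------------------------------------------------------------------------
# the TMLE itself
# ---------------------------------------------------------------------------


@dataclass
class TmleFit:
    """One counterfactual-mean estimate with influence-curve inference."""

    regime: Regime
    wave: int
    psi: float
    ic: np.ndarray
    se: float
    epsilons: list[float] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)
    outcome_scale: tuple[float, float] | None = None

    @property
    def n(self) -> int:
        return len(self.ic)


def _fluctuate(offset_logit: np.ndarray, target: np.ndarray, w: np.ndarray) -> float:
    """Weighted intercept-only logistic fluctuation: solve the score in eps.

    Maximizes sum_i w_i [T_i log p_i + (1-T_i) log(1-p_i)] with
    p_i = expit(offset_i + eps).  Returns eps (capped at |eps| <= 30 under
    separation).
    """
    act = w > 0
    o, t, ww = offset_logit[act], target[act], w[act]
    if len(o) == 0:
        raise ValueError("no regime followers with positive weight at targeting step")
    eps = 0.0
    for _ in range(200):
        p = expit(o + eps)
        score = float((ww * (t - p)).sum())
        info = float((ww * p * (1 - p)).sum())
        if abs(score) < 1e-12 * max(1.0, ww.sum()):
            break
        if info <= 1e-300:
            break
        step = np.clip(score / info, -5.0, 5.0)
        eps = float(np.clip(eps + step, -30.0, 30.0))
        if abs(step) < 1e-14:
            break
    return eps


def scale_continuous_outcome(
    y: np.ndarray, bounds: tuple[float, float] | None = None
) -> tuple[np.ndarray, tuple[float, float]]:
    """Map a continuous outcome to [0, 1]; values outside bounds are clipped.

    Returns the scaled vector and the bounds actually used (observed
    min/max when none are given).  The TMLE runs on the unit scale and
    back-transforms psi, ic and se by the range.
    """
    y = np.asarray(y, float)
    if bounds is None:
        bounds = (float(np.nanmin(y)), float(np.nanmax(y)))
    lo, hi = bounds
    if not hi > lo:
        raise ValueError("outcome bounds must satisfy max > min (constant outcome?)")
    if np.nanmin(y) < lo or np.nanmax(y) > hi:
        logger.warning("continuous outcome clipped to bounds [%g, %g]", lo, hi)
    return np.clip((y - lo) / (hi - lo), 0.0, 1.0), bounds


def tmle_counterfactual_mean(
    table: CohortTable,
    regime: Regime,
    wave: int,
    q_engine=None,
    g: TreatmentMechanism | None = None,
    outcome: str | None = None,
    outcome_bounds: tuple[float, float] | None = None,
) -> TmleFit:
    """ICE-TMLE of E[Y_wave] under a static regime (or the observed mean).

    Backward over the treatment nodes relevant to the wave: (i) regress the
    current iterated outcome on the history (including the treatment node)
    among subjects whose prior treatments follow the regime, (ii) predict
    with the treatment set to the regime value, (iii) fluctuate the
    prediction through a weighted intercept-only logistic submodel with
    weights follower-indicator / cumulative-g, (iv) recurse.  psi is the
    mean of the final targeted prediction.

    For the sentinel "observed" regime, psi is the empirical mean of the
    outcome and the influence curve is Y - psi (no targeting).
    """
    specs = table.node_specs
    if outcome is None:
        cands = [s for s in specs if s.role == "outcome" and s.wave == wave and s.value_kind == "binary"]
        if not cands:
            raise ValueError(f"no binary outcome node at wave {wave}")
        ynode = cands[0]
    else:
        ynode = table.spec(outcome)
        if ynode.wave != wave:
            raise ValueError(f"outcome node {ynode.name!r} is at wave {ynode.wave}, not {wave}")
    continuous = ynode.value_kind == "continuous"

    yvals = table.values(ynode.name)
    _require_complete(table, [ynode.name])
    scale: tuple[float, float] | None = None
    if continuous:
        yvals, scale = scale_continuous_outcome(yvals, outcome_bounds)

    n = table.n
    if regime.is_observed:
        psi_s = float(yvals.mean())
        ic_s = yvals - psi_s
        if continuous:
            lo, hi = scale
            return TmleFit(regime, wave, lo + psi_s * (hi - lo), ic_s * (hi - lo),
                           float(np.std(ic_s * (hi - lo), ddof=1) / np.sqrt(n)),
                           outcome_scale=scale)
        return TmleFit(regime, wave, psi_s, ic_s, float(np.std(ic_s, ddof=1) / np.sqrt(n)))

    if g is None:
        raise ValueError("a fitted TreatmentMechanism is required for static regimes")
    if q_engine is None:
        raise ValueError("a q_engine is required for static regimes")
    # treatment nodes preceding the outcome (within-wave ordering L, A, Y)
    tnodes = [s for s in g.nodes if s.wave <= wave]
    a = regime.assignments
    if len(a) != len(tnodes):
        raise ValueError(f"regime length {len(a)} != {len(tnodes)} treatment nodes for wave {wave}")

    tvals = {s.name: table.values(s.name) for s in tnodes}
    for s in tnodes:
        _require_complete(table, [s.name])

    # follower indicators and cumulative g through each node
    follow = np.ones((len(tnodes) + 1, n))  # follow[t] = through node t-1
    for t, s in enumerate(tnodes):
        follow[t + 1] = follow[t] * (tvals[s.name] == a[t])
    cumg = np.ones(n)
    cumgs = []
    for t, s in enumerate(tnodes):
        g1 = g.prob(s.name, table)
        cumg = cumg * np.where(a[t] == 1, g1, 1.0 - g1)
        cumgs.append(cumg.copy())

    q_cur = yvals.copy()
    steps: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []  # (w, target, q_star)
    epsilons: list[float] = []
    q_diag: list[dict] = []
    for t in range(len(tnodes) - 1, -1, -1):
        node = tnodes[t]
        hist = history_names(specs, node)
        _require_complete(table, hist)
        cols = hist + [node.name]
        X = table.df[cols].to_numpy(dtype=float)
        fit_rows = follow[t] == 1
        if not fit_rows.any():
            raise ValueError(
                f"no subjects follow regime {regime.label()} through node {node.name}: positivity violation"
            )
        engine_fit = q_engine.fit(X[fit_rows], q_cur[fit_rows])
        Xset = X.copy()
        Xset[:, -1] = a[t]
        q_pred = np.clip(np.asarray(engine_fit.predict(Xset), float), _QCLIP, 1 - _QCLIP)
        if not (follow[t + 1] == 1).any():
            raise ValueError(
                f"no subjects follow regime {regime.label()} through node {node.name}: positivity violation"
            )
        w = follow[t + 1] / cumgs[t]
        eps = _fluctuate(logit(q_pred), q_cur, w)
        q_star = expit(logit(q_pred) + eps)
        steps.append((w, q_cur.copy(), q_star))
        epsilons.append(eps)
        q_diag.append({
            "node": node.name,
            "n_fit": int(fit_rows.sum()),
            "n_followers": int(follow[t + 1].sum()),
            "epsilon": eps,
            "max_weight": float(w.max()),
        })
        q_cur = q_star

    psi_s = float(q_cur.mean())
    ic_s = q_cur - psi_s
    for w, target, q_star in steps:
        ic_s = ic_s + w * (target - q_star)
    se_s = float(np.std(ic_s, ddof=1) / np.sqrt(n))
    diagnostics = {"q_steps": q_diag[::-1], "g": g.diagnostics, "truncation": list(g.truncation)}
    if continuous:
        lo, hi = scale
        return TmleFit(regime, wave, lo + psi_s * (hi - lo), ic_s * (hi - lo),
                       se_s * (hi - lo), epsilons[::-1], diagnostics, scale)
    return TmleFit(regime, wave, psi_s, ic_s, se_s, epsilons[::-1], diagnostics)


# ---------------------------------------------------------------------------
# independent comparators (testing oracles, not estimators)
# ---------------------------------------------------------------------------


def _empirical_cond(table: CohortTable, names: list[str]):
    """Conditional frequency lookup P(node=1 | full preceding history)."""
    arr = table.df[names].to_numpy(dtype=float)
    tables: list[dict[tuple, tuple[float, int]]] = []
    for k in range(len(names)):
        d: dict[tuple, list[float]] = {}
        keys = [tuple(row) for row in arr[:, :k]]
        for key, v in zip(keys, arr[:, k]):
            s = d.setdefault(key, [0.0, 0])
            s[0] += v
            s[1] += 1
        tables.append({key: (s[0] / s[1], s[1]) for key, s in d.items()})
    return tables


def gformula_oracle(
    source: CohortTable | StructuralModel,
    regime: Regime,
    wave: int,
    on_empty: str = "marginal",
) -> float:
    """Exact plug-in g-formula by exhaustive enumeration over all histories.

    ``source`` is either a cohort table (empirical conditional frequencies,
    all nodes binary) or a structural model (exact conditional
    probabilities).  Treatments are fixed to the regime.  For empirical
    tables, a history stratum with no observations uses the node's marginal
    mean when ``on_empty="marginal"`` and raises otherwise.
    """
    if regime.is_observed:
        raise ValueError("the g-formula oracle requires a static regime")
    model = source if isinstance(source, StructuralModel) else None
    specs = source.node_specs
    ynodes = [s for s in specs if s.role == "outcome" and s.wave == wave and s.value_kind == "binary"]
    if not ynodes:
        raise ValueError(f"no binary outcome node at wave {wave}")
    upto = [s.name for s in specs].index(ynodes[0].name)
    path = specs[: upto + 1]
    for s in path:
        if s.value_kind != "binary":
            raise ValueError(f"oracle requires binary nodes; {s.name!r} is continuous")
    if 2 ** len(path) > 2**16:
        raise ValueError("history space exceeds 2^16; oracle not applicable")
    tnames = [s.name for s in specs if s.role == "treatment" and s.wave <= wave]
    a = dict(zip(tnames, regime.assignments))
    if len(regime.assignments) != len(tnames):
        raise ValueError("regime length does not match treatment nodes")

    if model is None:
        _require_complete(source, [s.name for s in path])
        cond = _empirical_cond(source, [s.name for s in path])
        marg = [float(source.df[s.name].mean()) for s in path]

        def p_one(k: int, hist: tuple) -> float:
            entry = cond[k].get(hist)
            if entry is None:
                if on_empty == "marginal":
                    return marg[k]
                raise ValueError(f"empty history stratum at node {path[k].name}: {hist}")
            return entry[0]

    else:

        def p_one(k: int, hist: tuple) -> float:
            eq = model.equations[path[k].name]
            cols = {s.name: np.array([v]) for s, v in zip(path, hist)}
            return float(eq.prob(cols)[0])

    total = 0.0
    stack: list[tuple[int, tuple, float]] = [(0, (), 1.0)]
    while stack:
        k, hist, wgt = stack.pop()
        if wgt == 0.0:
            continue
        name = path[k].name
        if k == upto:
            total += wgt * p_one(k, hist)
            continue
        if name in a:
            stack.append((k + 1, hist + (float(a[name]),), wgt))
        else:
            p = p_one(k, hist)
            stack.append((k + 1, hist + (1.0,), wgt * p))
            stack.append((k + 1, hist + (0.0,), wgt * (1.0 - p)))
    return total


def iptw_comparator(
    table: CohortTable, regime: Regime, wave: int, g: TreatmentMechanism
) -> float:
    """Horvitz-Thompson mean: average of Y * I(regime followed) / cumulative g."""
    if regime.is_observed:
        ynode = [s for s in table.node_specs if s.role == "outcome" and s.wave == wave][0]
        return float(table.values(ynode.name).mean())
    tnodes = [s for s in g.nodes if s.wave <= wave]
    a = regime.assignments
    follow = np.ones(table.n)
    for t, s in enumerate(tnodes):
        follow *= table.values(s.name) == a[t]
    cumg = g.cumulative_g(table, regime, through=len(tnodes) - 1)
    ynode = [s for s in table.node_specs if s.role == "outcome" and s.wave == wave and s.value_kind == "binary"][0]
    y = table.values(ynode.name)
    return float(np.mean(y * follow / cumg))
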