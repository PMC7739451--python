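"""End-to-end analysis pipeline: read -> impute -> TMLE per regime -> pool.

One :class:`AnalysisConfig` drives the whole run.  The report mirrors the
study's presentation: a treatment-pattern frequency table, pooled
counterfactual means per regime, and the five regime contrasts

    (1,1) vs (0,0);  (1,1) vs observed;  (1,1) vs (1,0);
    (1,0) vs (0,0);  (1,0) vs observed

at waves 2 and 3, each pooled over the imputations by Rubin's rules.  Every
source of randomness (imputation chains, cross-validation folds) derives
from the single master seed, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, Field

from . import __version__
from .cohort import CohortTable, read_cohort, regime_pattern_counts
from .contrasts import ATE, RR, ContrastResult, pooled_contrast
from .mi import impute, pool
from .nodes import load_node_specs
from .superlearner import SuperLearnerEngine, library_from_names
from .synthetic import widen_exposure
from .tmle import Regime, TmleFit, fit_treatment_mechanism, tmle_counterfactual_mean

logger = logging.getLogger(__name__)

STATIC_REGIMES = [(0, 0), (1, 0), (1, 1)]
CONTRAST_ROWS = [
    ((1, 1), (0, 0)),
    ((1, 1), "observed"),
    ((1, 1), (1, 0)),
    ((1, 0), (0, 0)),
    ((1, 0), "observed"),
]


class AnalysisConfig(BaseModel):
    """Configuration for one pipeline run (YAML-serializable)."""

    cohort_csv: Optional[str] = None
    node_spec_yaml: Optional[str] = None
    m: int = Field(5, ge=2, description="number of imputations (Rubin needs >= 2)")
    burnin: int = Field(10, ge=1)
    seed: int = 0
    truncation: tuple[float, float] = (0.01, 0.99)
    learners: list[str] = ["mean", "glm", "glm_ridge"]
    folds: Optional[int] = None
    waves: list[int] = [2, 3]
    pool_scale: Literal["log", "identity"] = "log"
    exposure: Literal["control_only", "control_or_reliever"] = "control_only"
    outcome: Literal["symptoms", "fev1_fvc"] = "symptoms"
    continuous_outcome_node: str = "lfr3"
    drop_nodes: list[str] = []

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


class ContrastRow(BaseModel):
    numerator: str
    denominator: str
    measure: str
    wave: int
    estimate: float
    ci_low: float
    ci_high: float
    m: int
    df: float
    within_var: float
    between_var: float
    total_var: float
    pool_scale: str


class RegimeMeanRow(BaseModel):
    regime: str
    wave: int
    psi: float
    ci_low: float
    ci_high: float


class Report(BaseModel):
    """Schema-validated pipeline output."""

    version: str
    n: int
    m: int
    seed: int
    outcome: str
    exposure: str
    waves: list[int]
    treatment_patterns: dict[str, int]
    regime_means: list[RegimeMeanRow]
    contrasts: list[ContrastRow]
    diagnostics: dict


def _engine(config: AnalysisConfig, binary: bool, seed: int) -> SuperLearnerEngine:
    lib = library_from_names(config.learners, binary=binary)
    return SuperLearnerEngine(lib, V=config.folds, seed=seed)


def _fit_all(
    config: AnalysisConfig, tables: list[CohortTable], outcome_kind: str
) -> tuple[dict, list]:
    """Per-imputation g + TMLE fits for every regime and wave."""
    waves = config.waves if outcome_kind == "symptoms" else [3]
    fits: dict[tuple, list[TmleFit]] = {}
    diags = []
    for i, tab in enumerate(tables):
        eng_seed = config.seed * 997 + i  # deterministic per-imputation stream
        g = fit_treatment_mechanism(tab, _engine(config, True, eng_seed), config.truncation)
        diags.append({"imputation": i, "g": g.diagnostics})
        for wave in waves:
            kwargs: dict = {}
            if outcome_kind == "fev1_fvc":
                kwargs["outcome"] = config.continuous_outcome_node
            for reg in STATIC_REGIMES + ["observed"]:
                r = Regime(tuple(reg) if reg != "observed" else "observed")
                fit = tmle_counterfactual_mean(
                    tab, r, wave,
                    q_engine=_engine(config, True, eng_seed + 13 * wave),
                    g=g,
                    **kwargs,
                )
                fits.setdefault((reg if reg == "observed" else tuple(reg), wave), []).append(fit)
    return fits, diags


def _report(config: AnalysisConfig, table: CohortTable, outcome_kind: str) -> Report:
    measure = RR if outcome_kind == "symptoms" else ATE
    waves = config.waves if outcome_kind == "symptoms" else [3]
    imputed = impute(table, m=config.m, seed=config.seed, burnin=config.burnin)
    fits, diags = _fit_all(config, imputed.tables, outcome_kind)

    means = []
    for (reg, wave), flist in fits.items():
        pe = pool([(f.psi, f.se**2) for f in flist])
        label = Regime(reg if reg == "observed" else tuple(reg)).label()
        means.append(RegimeMeanRow(regime=label, wave=wave, psi=pe.point,
                                   ci_low=pe.ci_low, ci_high=pe.ci_high))
    rows = []
    for num, den in CONTRAST_ROWS:
        for wave in waves:
            res: ContrastResult = pooled_contrast(
                fits[(num, wave)], fits[(den, wave)],
                measure=measure, scale=config.pool_scale,
            )
            rows.append(ContrastRow(
                numerator=res.numerator.label(),
                denominator=res.denominator.label(),
                measure=res.measure,
                wave=wave,
                estimate=res.estimate,
                ci_low=res.ci_low,
                ci_high=res.ci_high,
                m=res.m,
                df=res.pooled.df,
                within_var=res.pooled.within_var,
                between_var=res.pooled.between_var,
                total_var=res.pooled.total_var,
                pool_scale=res.scale,
            ))
    patterns = {
        "(" + ",".join(map(str, k)) + ")": v
        for k, v in sorted(regime_pattern_counts(table).items())
    }
    epsilons = {
        f"{Regime(r if r == 'observed' else tuple(r)).label()}@wave{w}": [f.epsilons for f in fl]
        for (r, w), fl in fits.items()
    }
    return Report(
        version=__version__,
        n=table.n,
        m=config.m,
        seed=config.seed,
        outcome=outcome_kind,
        exposure=config.exposure,
        waves=waves,
        treatment_patterns=patterns,
        regime_means=means,
        contrasts=rows,
        diagnostics={"per_imputation_g": diags, "epsilons": epsilons,
                     "truncation": list(config.truncation)},
    )


def _load_table(config: AnalysisConfig) -> CohortTable:
    if config.cohort_csv is None or config.node_spec_yaml is None:
        raise ValueError("config must reference cohort_csv and node_spec_yaml")
    specs = load_node_specs(config.node_spec_yaml)
    return read_cohort(config.cohort_csv, specs)


def _prepare(config: AnalysisConfig, table: CohortTable) -> CohortTable:
    if config.drop_nodes:
        from .synthetic import drop_columns

        table = drop_columns(table, config.drop_nodes)
    if config.exposure == "control_or_reliever":
        table = widen_exposure(table)
    return table


def run_analysis(config: AnalysisConfig, table: CohortTable | None = None) -> Report:
    """The main pipeline: symptoms outcome, control-medication exposure.

    ``table`` may be passed directly (programmatic/synthetic use); otherwise
    it is read from the configured CSV.
    """
    if table is None:
        table = _load_table(config)
    cfg = config.model_copy(update={"exposure": "control_only", "outcome": "symptoms"})
    return _report(cfg, _prepare(cfg, table), "symptoms")


def run_sensitivity(config: AnalysisConfig, table: CohortTable | None = None) -> Report:
    """Sensitivity pipeline: widened exposure and/or continuous lung function.

    With ``exposure="control_only"`` and ``outcome="symptoms"`` this is
    exactly :func:`run_analysis`.
    """
    if table is None:
        table = _load_table(config)
    return _report(config, _prepare(config, table), config.outcome)


def write_report(report: Report, out_dir: str | Path) -> Path:
    """Write report.json (canonical form), table4/5-like CSVs and diagnostics."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = report.model_dump()
    diagnostics = payload.pop("diagnostics")
    path = out / "report.json"
    path.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")
    (out / "diagnostics.json").write_text(json.dumps(diagnostics, sort_keys=True, indent=2) + "\n")

    import csv

    with open(out / "table4_like.csv", "w", newline="") as fh:
        wcsv = csv.writer(fh)
        wcsv.writerow(["treatment_pattern", "count", "percent"])
        for k, v in report.treatment_patterns.items():
            wcsv.writerow([k, v, f"{100 * v / report.n:.1f}"])
    with open(out / "table5_like.csv", "w", newline="") as fh:
        wcsv = csv.writer(fh)
        header = ["comparison", "measure"] + [
            f"wave{w}_estimate_95ci" for w in report.waves
        ]
        wcsv.writerow(header)
        bykey: dict[tuple[str, str], dict[int, ContrastRow]] = {}
        for row in report.contrasts:
            bykey.setdefault((row.numerator, row.denominator), {})[row.wave] = row
        for (num, den), waves in bykey.items():
            cells = []
            for w in report.waves:
                r = waves.get(w)
                cells.append("" if r is None else f"{r.estimate:.2f} ({r.ci_low:.2f}; {r.ci_high:.2f})")
            wcsv.writerow([f"{num} vs {den}", report.contrasts[0].measure] + cells)
    return path


def validate_report(path: str | Path) -> Report:
    """Load and schema-validate a report.json written by :func:`write_report`."""
    payload = json.loads(Path(path).read_text())
    payload.setdefault("diagnostics", {})
    return Report(**payload)
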