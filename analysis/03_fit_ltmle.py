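#!/usr/bin/env python
"""Main analysis: longitudinal TMLE of the five regime comparisons.

Runs the full pipeline (MI m=5 -> Super Learner -> TMLE -> Rubin pooling)
on the simulated cohort twice:

* **severity-blind** — the latent severity column is dropped before
  analysis, mirroring a study that cannot adjust for disease severity; and
* **severity-adjusted** — severity enters every regression, making the
  adjustment set sufficient for the generator.

The gap between the two runs is the structural confounding (reverse
causation) the severity-blind analysis inherits; the truth side-car from
01_simulate_cohort.py says where the estimates ought to land.

Outputs: results/main/{report.json, table4_like.csv, table5_like.csv, ...}
         results/main_severity_adjusted/...
"""

import json
from pathlib import Path

from solartmle.cohort import read_cohort
from solartmle.nodes import load_node_specs
from solartmle.pipeline import AnalysisConfig, run_analysis, write_report

SEED = 1
ROOT = Path(__file__).resolve().parent.parent / "results"


def show(tag: str, report, truth: dict) -> None:
    print(f"\n{tag}: pooled relative risks (95% CI), m={report.m}")
    for row in report.contrasts:
        print(
            f"  {row.numerator:>8} vs {row.denominator:<9} wave {row.wave}: "
            f"{row.estimate:.2f} ({row.ci_low:.2f}; {row.ci_high:.2f})"
        )
    rr3 = truth["(1,1)@wave3"]["risk"] / truth["(0,0)@wave3"]["risk"]
    print(f"  [generator truth for (1,1) vs (0,0) at wave 3: {rr3:.2f}]")


def main() -> None:
    specs = load_node_specs(ROOT / "cohort" / "node_spec.yaml")
    table = read_cohort(ROOT / "cohort" / "cohort.csv", specs)
    truth = json.loads((ROOT / "cohort" / "truth.json").read_text())

    blind_cfg = AnalysisConfig(seed=SEED, m=5, burnin=10,
                               learners=["mean", "glm", "glm_ridge"],
                               drop_nodes=["severity"])
    blind = run_analysis(blind_cfg, table=table)
    write_report(blind, ROOT / "main")
    show("severity-blind (the study's situation)", blind, truth)

    adj_cfg = blind_cfg.model_copy(update={"drop_nodes": []})
    adjusted = run_analysis(adj_cfg, table=table)
    write_report(adjusted, ROOT / "main_severity_adjusted")
    show("severity-adjusted (sufficient adjustment set)", adjusted, truth)

    b3 = next(r for r in blind.contrasts if (r.numerator, r.denominator, r.wave) == ("(1,1)", "(0,0)", 3))
    a3 = next(r for r in adjusted.contrasts if (r.numerator, r.denominator, r.wave) == ("(1,1)", "(0,0)", 3))
    print(
        f"\nsustained-vs-never at wave 3: blind {b3.estimate:.2f} vs adjusted {a3.estimate:.2f} — "
        "the systematic part of this gap is confounding by unmeasured severity "
        "(at n=121 sampling noise dominates; the replicate studies in "
        "05_benchmark.py separate the two)"
    )
    print(f"\nwrote reports under {ROOT}/main and {ROOT}/main_severity_adjusted")


if __name__ == "__main__":
    main()
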