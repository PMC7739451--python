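# solartmle

Longitudinal targeted maximum likelihood estimation (LTMLE) of the effect of
asthma **control medication** on **asthma symptoms** in a small prospective
cohort followed over three questionnaire waves (childhood to young
adulthood), with a synthetic cohort generator that provides exact
counterfactual ground truth for validating every stage of the pipeline.

## The problem

In observational longitudinal data, asthma medication use at one wave
affects symptoms at the next wave, which in turn affect later medication
use: time-varying confounding with treatment-confounder feedback. Standard
regression adjustment is biased here. The estimand is instead the
counterfactual risk of reporting symptoms under *static treatment regimes*
over the two waves with medication data:

- **(0,0)** — nobody takes control medication at either wave,
- **(1,0)** — everybody takes it at wave 1 only (early, unsustained),
- **(1,1)** — everybody takes it at both waves (early, sustained),
- **observed** — medication is taken as it actually was.

With nodes ordered `W, L1, A1, Y1, L2, A2, Y2, L3, Y3` (baseline
covariates, per-wave confounders, treatments, outcomes), the counterfactual
mean under regime `ā = (a1, a2)` is identified by the longitudinal
g-formula and estimated by the **iterated-conditional-expectation TMLE**:

1. set `Q̄ = Y` at the queried wave;
2. for treatment nodes from last to first: regress `Q̄` on the history
   among subjects following the regime so far, predict with `A_t = a_t`,
   then *target* the prediction with a weighted intercept-only logistic
   fluctuation, weights `I(Ā_t = ā_t) / ∏_{s≤t} g_s(a_s | past)` (the
   cumulative inverse probability of treatment, truncated to [0.01, 0.99]);
3. `ψ̂` is the mean of the final targeted prediction, and the influence
   curve `IC_i = Σ_t w_{t,i}(Q̄*_{t+1,i} − Q̄*_{t,i}) + Q̄*_{1,i} − ψ̂`
   gives `SE = sd(IC)/√n`.

Nuisance regressions (`Q̄` and `g`) are fitted by a **Super Learner** — a
cross-validated convex stacking of an intercept-only model, main-terms and
pairwise-interaction logistic GLMs, and a ridge-regularized GLM. Missing
questionnaire data (MAR) are handled upstream by **chained-equations
multiple imputation** (m = 5) and estimates are combined by **Rubin's
rules**, with relative risks pooled on the log scale. Contrasts of two
regimes are reported as relative risks (binary symptom outcome) or
additive treatment effects (continuous FEV1s/FVC lung-function outcome)
with delta-method Wald CIs from the joint influence curve.

Because no individual-level cohort of this kind is publicly available, the
package ships a **structural-equation generator** calibrated to the study's
printed marginals (symptom prevalence 0.96/0.66/0.65 by wave, control
medication 0.55 then 0.15, per-node missingness 1–10%), including a latent
binary *severity* that raises both treatment and symptom probabilities —
the reverse-causation structure such cohorts are suspected of. Ground
truth under any regime comes from interventional Monte Carlo on the same
equations, so estimator bias and structural confounding can be separated.

## Worked example

```python
from solartmle.synthetic import default_solar_model, simulate, counterfactual_truth
from solartmle.pipeline import AnalysisConfig, run_analysis

model = default_solar_model()
table = simulate(model, 121, seed=1)            # cohort with MAR missingness
report = run_analysis(AnalysisConfig(seed=1, m=5), table=table)
for row in report.contrasts:
    print(row.numerator, "vs", row.denominator, "wave", row.wave,
          f"{row.estimate:.2f} ({row.ci_low:.2f}; {row.ci_high:.2f})")
truth = counterfactual_truth(model, (1, 1), 3).risk / counterfactual_truth(model, (0, 0), 3).risk
print("generator truth, (1,1) vs (0,0) at wave 3:", round(truth, 2))
```

prints (abridged):

```
(1,1) vs (0,0) wave 2 1.38 (1.13; 1.70)
(1,1) vs (0,0) wave 3 1.81 (1.32; 2.48)
(1,0) vs (0,0) wave 3 1.44 (1.08; 1.92)
...
generator truth, (1,1) vs (0,0) at wave 3: 1.32
```

i.e. at n = 121 the pooled sustained-vs-never relative risk for this draw
is 1.81 with a wide CI that covers the true 1.32 — single small-cohort
estimates are noisy, which is exactly what the replicate studies quantify
(over 200 replicate cohorts at n = 1000 the mean pooled RR is within 0.01
of truth with 96% CI coverage; see `analysis/05_benchmark.py`).

The numbered scripts under `analysis/` run the full narrative —
`01_simulate_cohort.py` (cohort + truth side-car), `02_impute.py`,
`03_fit_ltmle.py` (main regime comparisons, severity-blind and
severity-adjusted), `04_sensitivity.py` (widened exposure; lung-function
ATE), `05_benchmark.py` (estimator validation) — writing tables under
`results/`. A `solartmle` CLI exposes the same stages
(`simulate`, `impute`, `analyze`, `sensitivity`, `benchmark`).

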