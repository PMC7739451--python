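# Methods

## Data model

A cohort is a wide table, one row per subject, whose columns are *nodes*
with fixed temporal ordering `W, L1, A1, Y1, L2, A2, Y2, L3, Y3`: baseline
covariates `W`, per-wave time-varying confounders `L_t`, binary treatments
`A_t` at waves 1–2 (no medication data exists at the final wave), and
outcomes `Y_t` at all three waves. Within a wave the ordering is
`L_t → A_t → Y_t`: exposure and symptom recall both cover the preceding
twelve months, and treatment is taken to causally precede the same-wave
outcome, so the wave-2 estimand already includes `A2`. Earlier outcomes
(`Y1`, `Y2`) are intermediate outcomes that enter later treatment and
outcome regressions as ordinary history covariates; they are not censoring
or competing events. Binary cells are {0, 1, missing}; missingness is
handled entirely by the imputation stage.

### Outcome and exposure coding

The binary symptom outcome is the any-of-three composite of the GINA
symptom items (daytime cough/wheeze, nocturnal awakening, activity
limitation): any observed positive item gives 1; 0 requires all three
observed and negative; otherwise the composite is missing. The
missing-item rule is a declared choice — an observed symptom always wins,
and absence is never assumed for an unobserved item — which keeps the
composite's missingness compatible with the MAR assumption downstream.

Free-text medication reports are classified against a packaged lexicon of
active agents and combination products (reliever: SABA, SAMA and their
combinations; control: ICS, LABA, ICS+LABA combinations, leukotriene
antagonists, systemic corticosteroids, mast-cell stabilizers,
methylxanthines). Matching is exact-token and case-insensitive;
combination products are looked up as a whole *before* splitting on "+",
because a combination's class is not the class of its dominant component
(a SABA + mast-cell-stabilizer product is a reliever even though the
stabilizer alone is a controller). Unknown agents are logged and ignored
rather than aborting — real questionnaire text always contains strays.
Historic spelling variants present in the source word lists (e.g.
"salbuatmol", "cromocligic acid") are kept alongside the normalized
spellings. The main exposure is control-medication use; the widened
sensitivity exposure is control-or-reliever use.

## The synthetic cohort generator

The generator draws from explicit structural equations in the node
ordering above: logistic equations for binary nodes, Gaussian for the
continuous lung-function ratio, each node depending on named parents.
The packaged default emulates a panel of ~121 asthmatic children:

- baseline sex/SES/centre/parental-asthma frequencies and per-wave
  marginals (symptoms 0.96/0.66/0.65, control medication 0.55/0.15,
  reliever-only 0.16/0.25, hay fever 0.26–0.31) match the study's printed
  prevalence table; intercepts were calibrated by large-n simulation with
  coefficients fixed first, effect sizes never adjusted afterwards;
- a latent binary **severity** (prevalence 0.40) raises both treatment
  probabilities and symptom probabilities, generating the
  reverse-causation confounding such cohorts are suspected of. Severity
  is emitted as a column so an analysis can include it (sufficient
  adjustment set, identifiable estimand — the setting of the validation
  studies) or drop it (the study's situation);
- treatment effects are log-odds coefficients on later outcomes, harmful
  by default (`A1: +0.30`, `A2: +0.60`, giving a true sustained-vs-never
  RR ≈ 1.32 at wave 3) and configurable, including the null;
- treatment propensities are clipped into [0.05, 0.95] by construction, so
  positivity holds in every generated cohort (for the default
  coefficients the clip never binds and the true propensities are exactly
  logistic);
- "reliever-only" indicators are gated to zero when same-wave control
  medication is taken (structural impossibility), are listed as
  next-wave covariates to respect the block ordering, and have no
  structural effect on symptoms — which is what makes the widened-exposure
  sensitivity analysis a pure dilution;
- MAR missingness: each maskable node has a logistic missingness model
  whose predictors are restricted to always-observed nodes (sex, centre),
  with rates matching the study's per-node NA counts (0.8%–10.7%;
  the continuous spirometry outcome 10%).

Ground truth for any regime is interventional Monte Carlo: re-run the
equations with treatment nodes fixed (missingness never applied), average
the outcome. For all-binary models an exhaustive enumeration over the
2^k history space gives the exact value; the MC and enumeration routes
agree to Monte-Carlo error, which is itself a test.

What the generator does **not** emulate: dropout across waves (the panel
is fixed), questionnaire wording effects, continuous-time medication
switching, dose/adherence, and any joint-distribution feature of the real
confounders beyond their marginals and the chosen dependence structure —
the real study never published a joint distribution, so the dependence
structure here is a package choice. Passing tests therefore demonstrate
correctness of the *estimator machinery* under a realistic data law, not
fidelity to the unavailable cohort.

## Multiple imputation

Chained equations over nodes in temporal order, predictor set = all other
nodes, 10 burn-in sweeps, m = 5 by default; each imputation runs an
independent chain seeded from a substream of the master seed. Binary
nodes: ridge-stabilized (λ = 0.01) weighted logistic fits, coefficients
drawn from the asymptotic posterior, then Bernoulli draws. Continuous
nodes: predictive-mean matching with 5 donors (type-1 matching: donor
predictions at the posterior mean, recipient predictions at the drawn
coefficients). Observed cells are never modified; a table without
missingness returns m identical copies. Outcome nodes *are* imputed —
the impute-then-analyse design analyses all subjects — and the imputation
engine reports (rather than hides) non-converged component fits. Nodes
that are ≥50% missing or fully missing are rejected.

Rubin's rules: pooled point = mean of points; total variance
`T = W̄ + (1 + 1/m) B`; degrees of freedom by Barnard–Rubin when a
complete-data df is supplied, otherwise its large-sample limit
`(m−1)(1 + W̄/((1+1/m)B))²`; 95% CI `point ± t_df √T`. Relative risks are
pooled on the log-RR scale and exponentiated (variance-stabilizing and
standard for ratio estimands); a config switch `pool_scale: identity`
pools the RR directly, which produces the symmetric intervals some
software prints — both are exposed because published intervals of this
kind are often symmetric on the RR scale, suggesting identity-scale
pooling there.

## Super Learner

V-fold cross-validated stacking; V = 10, dropping to 5 below n = 40. Fold
assignment depends only on (n, V, seed). Default library: intercept-only,
main-terms logistic GLM, all-pairwise-interactions GLM, ridge GLM (λ = 1)
— deliberately small, deterministic, and adequate at n ≈ 121; extensible
by name through the config. The learners are purpose-built weighted
quasi-binomial GLMs because the ICE targets are fractional (previous-step
probabilities), which off-the-shelf classifiers refuse. Weights are found
by non-negative least squares on the CV prediction matrix (renormalized to
the simplex) and refined by simplex-constrained minimization of the
declared CV loss (log-loss for binary, MSE for continuous); the optimized
combination is then compared against every single-learner vertex and the
best candidate wins, ties resolving toward earlier library entries. This
guarantees the stacking inequality — ensemble CV risk ≤ best single
learner — as an invariant rather than an aspiration. A learner that
raises anywhere is assigned weight zero with a logged warning. Binary-loss
predictions are clipped to [1e-6, 1−1e-6].

## TMLE numerics

- Iterated regressions are fitted among subjects whose treatments match
  the regime through the *previous* node, with the current treatment node
  included as a covariate and set to its regime value at prediction
  (standard ICE convention; pinned by tests).
- The fluctuation is a weighted intercept-only logistic submodel (weights
  in the fitting, not a clever covariate in the regressor) — numerically
  stabler at n ≈ 121 and solving the same score equation. The 1-D Newton
  solve runs to |score| < 1e-12, is step-damped, and caps |ε| ≤ 30 under
  separation; the resulting |mean IC| < 1e-8 is asserted for every fit.
- g-truncation defaults to [0.01, 0.99] and is reported in the output
  along with per-node positivity diagnostics (min/max predicted g, counts
  outside bounds). Zero regime-followers at any node raise a
  positivity-violation error rather than returning a number.
- Iterated predictions are clipped to [1e-6, 1−1e-6] before the logit.
- Continuous outcomes are mapped to [0, 1] by observed (or supplied)
  bounds, estimated on that scale, and back-transformed; contrasts are
  additive treatment effects.
- The "no intervention" comparator is the empirical outcome mean with
  influence curve `Y − ψ̂`. The alternative reading — g-computation under
  the natural treatment mechanism — equals the same population quantity
  and is obtainable as `counterfactual_truth(model, "observed", ...)` on
  the synthetic side; the empirical mean is what the report uses.

## Validation studies (sizes used)

- **Triangulation**: n = 50,000 all-binary cohort (one baseline, one
  confounder per wave, all conditionals inside (0.2, 0.8) so every
  stratum is populated), saturated stratum-mean fits. TMLE equals the
  exhaustive g-formula plug-in to ≈ 1e-14 (they are algebraically
  identical in this regime) and IPTW agrees to sampling error.
- **Recovery**: 200 replicate cohorts, n = 1000, default generator with
  MAR missingness, full MI(m = 5, 10 sweeps) → GLM-engine TMLE → Rubin
  pooling, against a 10⁶-draw MC truth; observed bias ≈ 0.003 on a truth
  RR of 1.32 and 95%-CI coverage ≈ 0.96. GLM engines are used in the
  replicates because the generator's conditionals are logistic, so they
  are correctly specified and fast; the Super Learner engine is exercised
  at study size elsewhere.
- **Double robustness**: 200 replicates, n = 1000, complete data; bias
  stays within Monte-Carlo error when the outcome regressions are correct
  and g is intercept-only, and vice versa.

## Known limitations

- The generator's joint confounder structure is a modelling choice; only
  marginals are calibrated to published counts.
- The widened-exposure counterfactual is analysed as a recoded treatment;
  a structural definition of "assign *some* medication" is not attempted
  (which medication would be assigned is ill-posed).
- The Super Learner library contains no tree/boosting learners by design;
  at n ≈ 121 their CV behaviour is erratic and the default library is
  meant to be deterministic.
- Influence-curve variance treats the nuisance fits as fixed; with
  estimated g this is typically conservative, consistent with the
  observed slight over-coverage.
- Dynamic regimes, stochastic interventions, survival outcomes and
  censoring processes are out of scope.
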