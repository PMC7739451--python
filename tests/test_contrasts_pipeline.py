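"""Regime contrasts, Rubin pooling of contrasts, and the pipeline report."""

import numpy as np
import pytest

from solartmle.contrasts import ATE, RR, contrast, pooled_contrast
from solartmle.pipeline import (
    CONTRAST_ROWS,
    AnalysisConfig,
    run_analysis,
    run_sensitivity,
    validate_report,
    write_report,
)
from solartmle.synthetic import default_solar_model, simulate, widen_exposure
from solartmle.tmle import Regime, TmleFit, fit_treatment_mechanism, tmle_counterfactual_mean
from solartmle.superlearner import GlmLearner


def _fake_fit(psi, ic, regime=(1, 1), wave=3):
    ic = np.asarray(ic, float)
    return TmleFit(Regime(regime), wave, psi, ic, float(np.std(ic, ddof=1) / np.sqrt(len(ic))))


def test_contrast_self_is_null(rng):
    ic = rng.normal(size=500)
    ic -= ic.mean()
    f = _fake_fit(0.4, ic)
    rr, v = contrast(f, f, RR)
    assert rr == 1.0 and v == 0.0
    ate, va = contrast(f, f, ATE)
    assert ate == 0.0 and va == 0.0


def test_contrast_ratio_and_difference(rng):
    ic1 = rng.normal(size=1000)
    ic0 = rng.normal(size=1000)
    f1 = _fake_fit(0.4, ic1 - ic1.mean())
    f0 = _fake_fit(0.2, ic0 - ic0.mean(), regime=(0, 0))
    rr, v = contrast(f1, f0, RR)
    assert rr == pytest.approx(2.0)
    assert v > 0
    ate, _ = contrast(f1, f0, ATE)
    assert ate == pytest.approx(0.2)


def test_contrast_zero_denominator(rng):
    ic = rng.normal(size=100)
    with pytest.raises(ValueError, match="zero"):
        contrast(_fake_fit(0.4, ic), _fake_fit(0.0, ic, regime=(0, 0)), RR)


def test_pooled_contrast_self_zero_width(rng):
    fits = []
    for _ in range(3):
        ic = rng.normal(size=200)
        fits.append(_fake_fit(0.5, ic - ic.mean()))
    res = pooled_contrast(fits, fits, RR)
    assert res.estimate == pytest.approx(1.0)
    assert res.ci_low == pytest.approx(1.0) and res.ci_high == pytest.approx(1.0)


def test_pool_scale_identity_symmetric(rng):
    fits1, fits0 = [], []
    for k in range(3):
        ic1 = rng.normal(size=300)
        ic0 = rng.normal(size=300)
        fits1.append(_fake_fit(0.5 + 0.01 * k, ic1 - ic1.mean()))
        fits0.append(_fake_fit(0.35 + 0.01 * k, ic0 - ic0.mean(), regime=(0, 0)))
    res = pooled_contrast(fits1, fits0, RR, scale="identity")
    # identity-scale pooling yields an interval symmetric about the estimate
    assert res.ci_high - res.estimate == pytest.approx(res.estimate - res.ci_low, rel=1e-9)
    res_log = pooled_contrast(fits1, fits0, RR, scale="log")
    assert res_log.estimate == pytest.approx(res.estimate, rel=1e-3)


@pytest.fixture(scope="module")
def small_report(solar_cohort):
    cfg = AnalysisConfig(seed=7, m=2, burnin=3, learners=["mean", "glm_ridge"])
    return cfg, run_analysis(cfg, table=solar_cohort)


def test_report_has_pinned_contrast_rows(small_report):
    """The five comparison rows appear for each analysed wave."""
    _, rep = small_report
    got = {(r.numerator, r.denominator, r.wave) for r in rep.contrasts}
    for num, den in CONTRAST_ROWS:
        lab_n = Regime(num if num == "observed" else tuple(num)).label()
        lab_d = Regime(den if den == "observed" else tuple(den)).label()
        for wave in (2, 3):
            assert (lab_n, lab_d, wave) in got
    assert len(rep.contrasts) == 10


def test_report_schema_roundtrip(small_report, tmp_path):
    _, rep = small_report
    path = write_report(rep, tmp_path)
    back = validate_report(path)
    assert back.n == rep.n and len(back.contrasts) == len(rep.contrasts)
    assert (tmp_path / "table4_like.csv").exists()
    assert (tmp_path / "table5_like.csv").exists()
    assert (tmp_path / "diagnostics.json").exists()


def test_report_estimates_within_ci(small_report):
    _, rep = small_report
    for row in rep.contrasts:
        assert row.ci_low <= row.estimate <= row.ci_high
        if row.measure == "RR":
            assert row.estimate > 0
        assert row.total_var >= row.within_var - 1e-12


def test_treatment_pattern_counts_in_report(small_report):
    _, rep = small_report
    assert set(rep.treatment_patterns) == {"(0,0)", "(0,1)", "(1,0)", "(1,1)"}
    assert sum(rep.treatment_patterns.values()) <= rep.n


def test_pipeline_determinism_same_seed(solar_cohort, tmp_path):
    cfg = AnalysisConfig(seed=11, m=2, burnin=2, learners=["mean", "glm_ridge"])
    p1 = write_report(run_analysis(cfg, table=solar_cohort), tmp_path / "a")
    p2 = write_report(run_analysis(cfg, table=solar_cohort), tmp_path / "b")
    assert p1.read_bytes() == p2.read_bytes()


def test_config_rejects_single_imputation():
    with pytest.raises(ValueError):
        AnalysisConfig(m=1)


def test_sensitivity_defaults_match_main(solar_cohort, small_report):
    cfg, rep = small_report
    rep2 = run_sensitivity(cfg, table=solar_cohort)
    assert rep2.model_dump() == rep.model_dump()


def test_sensitivity_continuous_outcome(solar_cohort):
    cfg = AnalysisConfig(seed=7, m=2, burnin=3, learners=["mean", "glm_ridge"], outcome="fev1_fvc")
    rep = run_sensitivity(cfg, table=solar_cohort)
    assert rep.waves == [3]
    assert all(r.measure == "ATE" for r in rep.contrasts)
    for row in rep.contrasts:
        assert row.ci_low <= row.estimate <= row.ci_high


def test_widened_exposure_dilutes_harmful_effect():
    """Reliever use has no structural effect, so adding it to the exposure
    pulls the estimated sustained-vs-never RR toward the null."""
    model = default_solar_model()
    tab = simulate(model, 20_000, seed=19, missingness=False)
    wide = widen_exposure(tab)

    def rr(t):
        g = fit_treatment_mechanism(t, GlmLearner())
        f1 = tmle_counterfactual_mean(t, Regime((1, 1)), 3, GlmLearner(), g)
        f0 = tmle_counterfactual_mean(t, Regime((0, 0)), 3, GlmLearner(), g)
        return f1.psi / f0.psi

    rr_control = rr(tab)
    rr_wide = rr(wide)
    assert rr_control > 1.1
    assert 1.0 < rr_wide < rr_control
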