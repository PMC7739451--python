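"""Regime contrasts: relative risks and additive treatment effects.

Contrasts are formed between two TMLE fits that share the same analysis
table and wave.  Because both fits carry per-subject influence curves, the
delta-method variance of the contrast uses the *joint* influence curve, so
the correlation between the two counterfactual means (estimated on the same
subjects) is accounted for.  Across imputations, relative risks are pooled
on the log scale by default (variance-stabilizing for ratio estimands) and
exponentiated; additive effects pool on the identity scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mi import PooledEstimate, pool
from .tmle import Regime, TmleFit

RR = "RR"
ATE = "ATE"


def contrast(
    fit1: TmleFit, fit0: TmleFit, measure: str = RR, scale: str = "log"
) -> tuple[float, float]:
    """Point estimate and variance for one contrast within one dataset.

    For ``measure="RR"``: estimate psi1/psi0 with delta-method variance of
    log RR, var(ic1/psi1 - ic0/psi0)/n (or of RR itself when
    ``scale="identity"``).  For ``measure="ATE"``: psi1 - psi0 with
    var(ic1 - ic0)/n.
    """
    if fit1.wave != fit0.wave or fit1.n != fit0.n:
        raise ValueError("contrasted fits must share wave and n")
    n = fit1.n
    if measure == ATE:
        d = fit1.ic - fit0.ic
        return float(fit1.psi - fit0.psi), float(np.var(d, ddof=1) / n)
    if measure != RR:
        raise ValueError(f"unknown measure {measure!r}")
    if fit0.psi == 0:
        raise ValueError("denominator counterfactual mean is zero; RR undefined")
    rr = fit1.psi / fit0.psi
    if scale == "log":
        d = fit1.ic / fit1.psi - fit0.ic / fit0.psi
        return float(rr), float(np.var(d, ddof=1) / n)
    d = fit1.ic / fit0.psi - rr * fit0.ic / fit0.psi
    return float(rr), float(np.var(d, ddof=1) / n)


@dataclass
class ContrastResult:
    """Pooled (over imputations) contrast between two regimes."""

    numerator: Regime
    denominator: Regime
    measure: str
    wave: int
    estimate: float
    ci_low: float
    ci_high: float
    m: int
    pooled: PooledEstimate
    scale: str = "log"

    def __post_init__(self) -> None:
        if self.measure == RR and self.estimate <= 0:
            raise ValueError("relative risk must be positive")
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("estimate outside its confidence interval")


def pooled_contrast(
    fits1: list[TmleFit],
    fits0: list[TmleFit],
    measure: str = RR,
    scale: str = "log",
    dfcom: float | None = None,
) -> ContrastResult:
    """Rubin-pool one contrast across the m imputations.

    ``scale`` applies to RR only: "log" pools log-RR and exponentiates
    (default); "identity" pools the RR directly, which yields the symmetric
    intervals some software reports.
    """
    if len(fits1) != len(fits0) or len(fits1) < 2:
        raise ValueError("need matching lists of >= 2 per-imputation fits")
    pairs = [contrast(f1, f0, measure, scale if measure == RR else "identity")
             for f1, f0 in zip(fits1, fits0)]
    if measure == RR and scale == "log":
        pts = [(float(np.log(est)), var) for est, var in pairs]
        pe = pool(pts, dfcom=dfcom)
        est, lo, hi = float(np.exp(pe.point)), float(np.exp(pe.ci_low)), float(np.exp(pe.ci_high))
    else:
        pe = pool(list(pairs), dfcom=dfcom)
        est, lo, hi = pe.point, pe.ci_low, pe.ci_high
    return ContrastResult(
        numerator=fits1[0].regime,
        denominator=fits0[0].regime,
        measure=measure,
        wave=fits1[0].wave,
        estimate=est,
        ci_low=lo,
        ci_high=hi,
        m=len(fits1),
        pooled=pe,
        scale=scale if measure == RR else "identity",
    )
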