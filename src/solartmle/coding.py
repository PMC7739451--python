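"""Outcome and exposure coding rules.

The binary symptom outcome follows the GINA control criteria available in
all three questionnaire waves: daytime symptoms (cough or wheeze), nighttime
symptoms (awaking due to wheeze or breathlessness), and limitation of
activity (breathlessness at rest or after activity).  A subject is coded 1
if any item is reported, 0 only if all three items are observed and
negative, and missing otherwise — an observed symptom always wins, and an
unobserved item can never be assumed absent.

The binary exposure is self-reported *control* medication intake (ICS,
LABA, leukotriene antagonists, systemic corticosteroids, mast-cell
stabilizers, methylxanthines), as opposed to *reliever* medication (SABA,
SAMA and their combinations).  Free-text agents are classified against a
packaged lexicon of active agents and combination products; combination
products are looked up as a whole before being split on "+".
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

logger = logging.getLogger(__name__)

MISSING = float("nan")

CONTROL = "control"
RELIEVER_ONLY = "reliever_only"
NONE = "none"


def _is_missing(v: float | None) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


@dataclass(frozen=True)
class SymptomItems:
    """The three GINA symptom items, each 0, 1 or missing (None/NaN)."""

    daytime: float | None
    nighttime: float | None
    activity_limitation: float | None

    def __post_init__(self) -> None:
        for v in (self.daytime, self.nighttime, self.activity_limitation):
            if not (_is_missing(v) or v in (0, 1)):
                raise ValueError(f"symptom item must be 0, 1 or missing, got {v!r}")

    def items(self) -> tuple[float | None, ...]:
        return (self.daytime, self.nighttime, self.activity_limitation)


def code_outcome(items: SymptomItems) -> float:
    """Composite any-symptom outcome: 1, 0, or NaN (missing).

    Any observed positive item yields 1; all-observed-negative yields 0;
    otherwise the composite is missing.
    """
    vals = items.items()
    if any(v == 1 for v in vals):
        return 1.0
    if any(_is_missing(v) for v in vals):
        return MISSING
    return 0.0


@dataclass(frozen=True)
class MedicationReport:
    """Free-text medication agents reported by one subject at one wave."""

    agents: tuple[str, ...] = ()
    none_reported: bool = False

    def __post_init__(self) -> None:
        if self.none_reported and self.agents:
            raise ValueError("none_reported=1 requires an empty agent list")


@dataclass(frozen=True)
class LungFunction:
    """Spirometric FEV1s and FVC volumes (litres) and their percent ratio."""

    fev1s: float
    fvc: float

    def __post_init__(self) -> None:
        if not (self.fvc > 0):
            raise ValueError("FVC must be positive")
        if not (0 < self.ratio_pct <= 150):
            raise ValueError(f"implausible FEV1s/FVC ratio {self.ratio_pct:.1f}%")

    @property
    def ratio_pct(self) -> float:
        return 100.0 * self.fev1s / self.fvc


def _normalize(agent: str) -> str:
    s = re.sub(r"\s+", " ", agent.strip().lower())
    s = re.sub(r"\s*\+\s*", " + ", s)
    return s


@dataclass
class MedicationLexicon:
    """Active-agent and combination-product map to {reliever, control}."""

    entries: dict[str, str]
    classes: dict[str, str] = field(default_factory=dict)

    @classmethod
    def packaged(cls) -> "MedicationLexicon":
        path = resources.files("solartmle").joinpath("data/medication_lexicon.csv")
        with resources.as_file(path) as p:
            df = pd.read_csv(p)
        entries = {}
        classes = {}
        for _, row in df.iterrows():
            key = _normalize(str(row["agent"]))
            entries[key] = str(row["category"])
            classes[key] = str(row["drug_class"])
        return cls(entries=entries, classes=classes)

    def lookup(self, agent: str) -> str | None:
        return self.entries.get(_normalize(agent))


def classify_medication(
    report: MedicationReport,
    lexicon: MedicationLexicon | None = None,
    unclassified: list[str] | None = None,
) -> str:
    """Classify one subject-wave report as control / reliever_only / none.

    A combination product ("fluticasone + salmeterol") is first looked up as
    a whole; only unknown combinations are split on "+" and classified by
    their components.  Control dominates: any control agent makes the report
    "control".  Unknown agent names are logged (and appended to
    ``unclassified`` if given) but never abort classification.
    """
    if lexicon is None:
        lexicon = MedicationLexicon.packaged()
    if report.none_reported or not report.agents:
        return NONE
    categories: list[str] = []
    for raw in report.agents:
        cat = lexicon.lookup(raw)
        if cat is not None:
            categories.append(cat)
            continue
        parts = [p for p in _normalize(raw).split(" + ") if p]
        part_cats = [lexicon.lookup(p) for p in parts] if len(parts) > 1 else [None]
        known = [c for c in part_cats if c is not None]
        if known:
            categories.extend(known)
        else:
            logger.warning("unclassified medication agent: %r", raw)
            if unclassified is not None:
                unclassified.append(raw)
    if CONTROL in categories:
        return CONTROL
    if "reliever" in categories:
        return RELIEVER_ONLY
    return NONE


def exposure_indicator(med_class: str, rule: str = "control_only") -> int:
    """Binary exposure from the medication class.

    ``control_only`` is the main-analysis coding (exposed = control
    medication); ``control_or_reliever`` is the widened sensitivity coding
    (exposed = any asthma medication).
    """
    if rule == "control_only":
        return int(med_class == CONTROL)
    if rule == "control_or_reliever":
        return int(med_class in (CONTROL, RELIEVER_ONLY))
    raise ValueError(f"unknown exposure rule {rule!r}")
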