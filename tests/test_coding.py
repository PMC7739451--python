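"""Outcome composite and medication classifier."""

import itertools
import math

import pytest

from solartmle.coding import (
    CONTROL,
    NONE,
    RELIEVER_ONLY,
    LungFunction,
    MedicationLexicon,
    MedicationReport,
    SymptomItems,
    classify_medication,
    code_outcome,
)

NAN = float("nan")


def _oracle_outcome(vals):
    """Independent statement of the any-of-three rule with missingness."""
    observed = [v for v in vals if not (isinstance(v, float) and math.isnan(v))]
    if 1 in observed:
        return 1.0
    if len(observed) == 3:
        return 0.0
    return NAN


@pytest.mark.parametrize("vals", list(itertools.product([0.0, 1.0, NAN], repeat=3)))
def test_outcome_truth_table(vals):
    """The composite matches exhaustive enumeration of the any-of-3 rule."""
    got = code_outcome(SymptomItems(*vals))
    want = _oracle_outcome(vals)
    if isinstance(want, float) and math.isnan(want):
        assert math.isnan(got)
    else:
        assert got == want


def test_outcome_examples():
    assert code_outcome(SymptomItems(1, 0, 0)) == 1
    assert code_outcome(SymptomItems(0, 0, 0)) == 0
    assert math.isnan(code_outcome(SymptomItems(0, NAN, 0)))


def test_outcome_monotone():
    """Raising any item from 0 to 1 never decreases the composite."""
    for vals in itertools.product([0.0, 1.0, NAN], repeat=3):
        base = code_outcome(SymptomItems(*vals))
        for i, v in enumerate(vals):
            if v == 0.0:
                up = list(vals)
                up[i] = 1.0
                raised = code_outcome(SymptomItems(*up))
                base_rank = -1 if math.isnan(base) else base
                assert raised >= base_rank


def test_outcome_rejects_bad_item():
    with pytest.raises(ValueError):
        SymptomItems(2, 0, 0)


@pytest.fixture(scope="module")
def lexicon():
    return MedicationLexicon.packaged()


@pytest.mark.parametrize(
    "agents, expected",
    [
        (["budesonide"], CONTROL),
        (["salbutamol"], RELIEVER_ONLY),
        (["salbuatmol"], RELIEVER_ONLY),  # questionnaire-era spelling
        (["fluticasone + salmeterol"], CONTROL),
        (["Fluticasone + Salmeterol"], CONTROL),  # case-insensitive
        (["fenoterol + cromoglicic acid"], RELIEVER_ONLY),  # combination looked up whole
        (["salbutamol", "budesonide"], CONTROL),  # control dominates
        (["ipratropium bromide", "terbutaline"], RELIEVER_ONLY),
    ],
)
def test_classifier_examples(lexicon, agents, expected):
    assert classify_medication(MedicationReport(tuple(agents)), lexicon) == expected


def test_classifier_none_reported(lexicon):
    assert classify_medication(MedicationReport((), none_reported=True), lexicon) == NONE
    with pytest.raises(ValueError):
        MedicationReport(("budesonide",), none_reported=True)


def test_unknown_agent_logged_not_fatal(lexicon):
    unclassified: list[str] = []
    got = classify_medication(
        MedicationReport(("notadrug", "budesonide")), lexicon, unclassified=unclassified
    )
    assert got == CONTROL
    assert unclassified == ["notadrug"]
    # a report containing only unknown agents falls through to "none"
    assert classify_medication(MedicationReport(("notadrug",)), lexicon) == NONE


def test_unknown_combination_splits_on_plus(lexicon):
    # unknown combination product: classified through its known components
    assert classify_medication(MedicationReport(("salbutamol + budesonide",)), lexicon) == CONTROL


def test_control_dominates_over_all_lexicon_pairs(lexicon):
    """Any control agent plus any reliever agent classifies as control."""
    controls = [a for a, c in lexicon.entries.items() if c == "control"]
    relievers = [a for a, c in lexicon.entries.items() if c == "reliever"]
    for c in controls:
        for r in relievers:
            assert classify_medication(MedicationReport((c, r)), lexicon) == CONTROL
            assert classify_medication(MedicationReport((r, c)), lexicon) == CONTROL


def test_lung_function_ratio():
    lf = LungFunction(fev1s=3.0, fvc=4.0)
    assert lf.ratio_pct == 75.0
    with pytest.raises(ValueError):
        LungFunction(fev1s=3.0, fvc=0.0)
    with pytest.raises(ValueError):
        LungFunction(fev1s=8.0, fvc=4.0)  # ratio 200% implausible
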