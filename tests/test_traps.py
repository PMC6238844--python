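"""Trap evaluation semantics, scoring, and failure distributions."""

import datetime as dt
import random
from collections import Counter

import pytest

from surveyvet import (
    ResponseRecord,
    TrapScore,
    TrapSpec,
    evaluate_trap,
    failure_distribution,
    opportunity_count,
    score_respondent,
    study2_trapspecs,
)

REF = dt.date(2016, 10, 15)


def _rec(answers):
    return ResponseRecord("r1", "ip1", 0, 600, answers=answers)


SEX_TRAP = TrapSpec(
    "sex_1", "linked_exclusive", ("sex", "pregnant"), {"forbidden": ["male", "yes"]}
)
FICT = TrapSpec("fict", "fictitious_item", ("fict_1",), {"fail_value": "yes"})
DATE = TrapSpec(
    "date", "fixed_answer", ("survey_date",),
    {"use_reference_date": True, "tolerance_days": 1},
)
DIAB = TrapSpec(
    "diab", "status_consistency", ("has_diabetes", "confirm"),
    {"forbidden": ["yes", "no"]},
)
TIMING = TrapSpec("timing", "timing")


def test_male_pregnant_fails():
    out = evaluate_trap(SEX_TRAP, _rec({"sex": "male", "pregnant": "yes"}), REF)
    assert out.status == "fail"
    out = evaluate_trap(SEX_TRAP, _rec({"sex": "female", "pregnant": "yes"}), REF)
    assert out.status == "pass"


def test_missing_member_is_not_applicable():
    for answers in (
        {"sex": None, "pregnant": "yes"},
        {"sex": "male", "pregnant": None},
    ):
        assert evaluate_trap(SEX_TRAP, _rec(answers), REF).status == "not_applicable"


def test_fictitious_item():
    assert evaluate_trap(FICT, _rec({"fict_1": "yes"}), REF).status == "fail"
    assert evaluate_trap(FICT, _rec({"fict_1": "no"}), REF).status == "pass"
    assert evaluate_trap(FICT, _rec({"fict_1": None}), REF).status == "not_applicable"


@pytest.mark.parametrize("offset", range(-3, 4))
def test_date_tolerance_window(offset):
    """±1 calendar day passes; anything beyond fails."""
    answer = (REF + dt.timedelta(days=offset)).isoformat()
    out = evaluate_trap(DATE, _rec({"survey_date": answer}), REF)
    assert out.status == ("pass" if abs(offset) <= 1 else "fail")


def test_garbage_date_fails_but_blank_does_not():
    assert evaluate_trap(DATE, _rec({"survey_date": "dunno"}), REF).status == "fail"
    assert (
        evaluate_trap(DATE, _rec({"survey_date": None}), REF).status
        == "not_applicable"
    )


def test_status_consistency_contradiction():
    fails = _rec({"has_diabetes": "yes", "confirm": "no"})
    assert evaluate_trap(DIAB, fails, REF).status == "fail"
    ok = _rec({"has_diabetes": "yes", "confirm": "yes"})
    assert evaluate_trap(DIAB, ok, REF).status == "pass"


def test_timing_trap_follows_flag():
    assert evaluate_trap(TIMING, _rec({}), REF, timing_flag=True).status == "fail"
    assert evaluate_trap(TIMING, _rec({}), REF, timing_flag=False).status == "pass"


def test_unknown_item_ref_is_hard_error():
    with pytest.raises(KeyError):
        evaluate_trap(FICT, _rec({"other": "yes"}), REF)


def _conscientious_record(ref=REF):
    answers = {"survey_date": ref.isoformat(), "sex": "female"}
    for i in range(1, 10):
        answers[f"fict_{i}"] = "no"
    for i in range(1, 14):
        answers[f"sextrap_{i}"] = "no"
    answers.update(
        has_diabetes="no", has_diabetes_confirm="no", dx_type1="no", dx_type2="no"
    )
    for item in (
        "age", "race", "marital", "education", "vignette_cause",
        "vignette_disease", "rating_responsibility", "rating_anger", "rating_blame",
    ):
        answers[item] = None
    return ResponseRecord("r1", "ip1", 1476489600, 1476490200, answers=answers)


def test_conscientious_respondent_scores_zero_of_26():
    specs = study2_trapspecs()
    score = score_respondent(specs, _conscientious_record(), REF, timing_flag=False)
    assert score.n_failures == 0
    assert score.n_opportunities == 26


def test_date_plus_timing_scores_two():
    specs = study2_trapspecs()
    rec = _conscientious_record()
    rec.answers["survey_date"] = (REF + dt.timedelta(days=3)).isoformat()
    score = score_respondent(specs, rec, REF, timing_flag=True)
    assert score.n_failures == 2
    assert set(score.failed_trap_ids) == {"date", "timing"}


def test_not_applicable_never_adds_failures():
    specs = study2_trapspecs()
    rec = _conscientious_record()
    base = score_respondent(specs, rec, REF).n_failures
    rec.answers["fict_3"] = None  # blank ≠ failure
    rec.answers["sex"] = None  # disables all 13 sex traps
    assert score_respondent(specs, rec, REF).n_failures == base == 0


def test_failure_distribution_all_zero():
    scores = [TrapScore(f"r{i}", 0, 26) for i in range(10)]
    assert failure_distribution(scores) == {0: 100.0}


def test_failure_distribution_matches_bruteforce_tally():
    rnd = random.Random(5)
    counts = [rnd.choice([0, 0, 0, 1, 1, 2, 3]) for _ in range(20)]
    scores = [
        TrapScore(f"r{i}", c, 26, tuple(f"t{j}" for j in range(c)))
        for i, c in enumerate(counts)
    ]
    dist = failure_distribution(scores)
    tally = Counter(counts)
    for k, pct in dist.items():
        assert pct == round(100.0 * tally.get(k, 0) / 20, 1)
    assert abs(sum(dist.values()) - 100.0) <= 0.2
    rnd.shuffle(scores)
    assert failure_distribution(scores) == dist


def test_failure_distribution_rejects_empty():
    with pytest.raises(ValueError):
        failure_distribution([])


def test_opportunity_count():
    specs = study2_trapspecs()
    assert opportunity_count(specs, 616) == 16016  # exceeds 16,000
    assert opportunity_count([], 100) == 0
    assert opportunity_count(specs, 1) == 26
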