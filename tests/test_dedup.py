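"""Duplicate-IP grouping, eligibility cascade, and transition detection."""

import random

import pytest

from surveyvet import (
    AttemptGroup,
    ResponseRecord,
    classify_eligibility,
    diabetes_status,
    group_attempts,
    attempt_histogram,
    qualifies_study1,
    screening_summary,
    transition_events,
)


def _rec(rid, ip, start, disease="none", adult=True):
    return ResponseRecord(rid, ip, start, start + 100, disease, adult)


def test_distinct_ips_make_singleton_groups():
    table = [_rec("a", "ip1", 0), _rec("b", "ip2", 5), _rec("c", "ip3", 9)]
    groups = group_attempts(table)
    assert [g.n_attempts for g in groups] == [1, 1, 1]
    assert {g.ip_key for g in groups} == {"ip1", "ip2", "ip3"}


def test_grouping_matches_bruteforce_oracle():
    """Grouping agrees with a quadratic pairwise-comparison reference."""
    rnd = random.Random(42)
    table = [
        _rec(f"r{i}", f"ip{rnd.randrange(12)}", rnd.randrange(10_000))
        for i in range(50)
    ]
    groups = group_attempts(table)
    # brute force: for each record collect all records sharing its ip_key
    for rec in table:
        mates = sorted(
            (o.response_id for o in table if o.ip_key == rec.ip_key)
        )
        group = next(g for g in groups if g.ip_key == rec.ip_key)
        assert sorted(r.response_id for r in group.attempts) == mates
    assert sum(g.n_attempts for g in groups) == len(table)


def test_within_group_order_and_tie_break():
    table = [
        _rec("b", "ip", 100),
        _rec("a", "ip", 100),  # same start: response_id breaks the tie
        _rec("c", "ip", 50),
    ]
    (group,) = group_attempts(table)
    assert [r.response_id for r in group.attempts] == ["c", "a", "b"]


def test_histogram_empty_without_duplicates():
    groups = group_attempts([_rec("a", "ip1", 0), _rec("b", "ip2", 1)])
    assert attempt_histogram(groups) == {}


def test_histogram_conserves_counts():
    rnd = random.Random(7)
    table = [
        _rec(f"r{i}", f"ip{rnd.randrange(20)}", rnd.randrange(10_000))
        for i in range(80)
    ]
    groups = group_attempts(table)
    hist = attempt_histogram(groups)
    dups = [g for g in groups if g.n_attempts >= 2]
    assert sum(hist.values()) == len(dups)
    assert sum(k * v for k, v in hist.items()) == sum(g.n_attempts for g in dups)


def test_eligibility_cascade():
    single_ok = AttemptGroup("ip1", [_rec("a", "ip1", 0, "diabetes")])
    assert classify_eligibility(single_ok, qualifies_study1) == {"a": "acceptable"}
    single_no = AttemptGroup("ip2", [_rec("b", "ip2", 0, "none")])
    assert classify_eligibility(single_no, qualifies_study1) == {
        "b": "single_nonqualified"
    }
    # a repeat IP is excluded wholesale, even the attempt that qualifies
    dup = AttemptGroup(
        "ip3", [_rec("c", "ip3", 0, "none"), _rec("d", "ip3", 30, "diabetes")]
    )
    assert classify_eligibility(dup, qualifies_study1) == {
        "c": "duplicate_excluded",
        "d": "duplicate_excluded",
    }


def test_transition_acquired_and_lost():
    acq = AttemptGroup(
        "ip", [_rec("a", "ip", 0, "none"), _rec("b", "ip", 45, "diabetes")]
    )
    (ev,) = transition_events(acq, diabetes_status)
    assert ev.direction == "acquired_condition"
    assert ev.latency_seconds == 45

    lost = AttemptGroup(
        "ip", [_rec("a", "ip", 0, "diabetes"), _rec("b", "ip", 12852, "none")]
    )
    (ev,) = transition_events(lost, diabetes_status)
    assert ev.direction == "lost_condition"
    assert ev.latency_seconds == 12852  # ≈ 3.57 h


def test_first_flip_wins():
    group = AttemptGroup(
        "ip",
        [
            _rec("a", "ip", 0, "none"),
            _rec("b", "ip", 50, "diabetes"),
            _rec("c", "ip", 90, "none"),  # a second flip is not reported
        ],
    )
    events = transition_events(group, diabetes_status)
    assert len(events) == 1
    assert events[0].direction == "acquired_condition"
    assert events[0].latency_seconds == 50


def test_blank_status_is_skipped_not_flipped():
    group = AttemptGroup(
        "ip",
        [
            _rec("a", "ip", 0, None),  # qualification left blank
            _rec("b", "ip", 60, "diabetes"),
            _rec("c", "ip", 120, "diabetes"),
        ],
    )
    assert transition_events(group, diabetes_status) == []


def test_constant_status_groups_emit_no_event():
    group = AttemptGroup(
        "ip", [_rec("a", "ip", 0, "asthma"), _rec("b", "ip", 9, "heart_disease")]
    )
    assert transition_events(group, diabetes_status) == []


def test_summary_partition_and_order_invariance():
    rnd = random.Random(3)
    table = [
        _rec(
            f"r{i}",
            f"ip{rnd.randrange(30)}",
            rnd.randrange(10_000),
            rnd.choice(["none", "diabetes", "asthma"]),
            rnd.random() < 0.9,
        )
        for i in range(100)
    ]
    s = screening_summary(table)
    assert (
        s.single_attempt_nonqualified + s.acceptable + s.duplicate_responses
        == s.total_responses
        == 100
    )
    shuffled = list(table)
    rnd.shuffle(shuffled)
    assert screening_summary(shuffled).to_dict() == s.to_dict()


def test_summary_of_empty_table_is_all_zero():
    s = screening_summary([])
    assert s.total_responses == 0
    assert s.acceptable == 0
    assert s.attempt_histogram == {}
    assert s.mean_attempts_per_duplicate_ip == 0.0


def test_classification_matches_bruteforce_reference():
    """On a small table, the cascade equals a pairwise re-derivation."""
    rnd = random.Random(99)
    table = [
        _rec(
            f"r{i}",
            f"ip{rnd.randrange(40)}",
            rnd.randrange(10_000),
            rnd.choice(["none", "diabetes"]),
        )
        for i in range(100)
    ]
    classes = {}
    for g in group_attempts(table):
        classes.update(classify_eligibility(g, qualifies_study1))
    for rec in table:
        n_same_ip = sum(1 for o in table if o.ip_key == rec.ip_key)
        if n_same_ip >= 2:
            expected = "duplicate_excluded"
        elif qualifies_study1(rec):
            expected = "acceptable"
        else:
            expected = "single_nonqualified"
        assert classes[rec.response_id] == expected
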