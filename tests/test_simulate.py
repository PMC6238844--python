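"""Generator contracts: determinism, ledger recovery, parameter recovery."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from surveyvet import (
    CohortConfig,
    TimingRule,
    generate_cohort,
    group_attempts,
    classify_eligibility,
    qualifies_study1,
    score_respondent,
    screening_summary,
    study2_schema,
    study2_trapspecs,
    timing_flags,
    write_responses,
)


def test_empty_cohort():
    records, ledger = generate_cohort(CohortConfig(n_respondents=0, seed=1))
    assert records == []
    assert ledger["archetype"] == {}


def test_same_seed_is_byte_identical(tmp_path):
    cfg = CohortConfig(n_respondents=60, seed=42)
    a, _ = generate_cohort(cfg)
    b, _ = generate_cohort(CohortConfig(n_respondents=60, seed=42))
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    write_responses(pa, a, study2_schema())
    write_responses(pb, b, study2_schema())
    assert pa.read_bytes() == pb.read_bytes()


def test_different_seeds_differ():
    a, _ = generate_cohort(CohortConfig(n_respondents=60, seed=1))
    b, _ = generate_cohort(CohortConfig(n_respondents=60, seed=2))
    assert [r.start_time for r in a] != [r.start_time for r in b]


def test_mixture_validation():
    with pytest.raises(ValueError, match="sums to"):
        CohortConfig(archetype_mixture={"conscientious": 0.5})
    with pytest.raises(ValueError, match="unknown archetype"):
        CohortConfig(archetype_mixture={"saint": 1.0})
    with pytest.raises(ValueError, match="unknown replica"):
        CohortConfig(replica="study3")


def test_pure_conscientious_cohort_is_clean():
    """All-conscientious mixture: no duplicate IPs and no trap failures."""
    cfg = CohortConfig(
        n_respondents=120, archetype_mixture={"conscientious": 1.0}, seed=5
    )
    records, ledger = generate_cohort(cfg)
    assert set(ledger["archetype"].values()) == {"conscientious"}
    summary = screening_summary(records)
    assert summary.duplicate_responses == 0
    specs = [s for s in study2_trapspecs() if s.category != "timing"]
    for rec in records:
        assert score_respondent(specs, rec).n_failures == 0


def test_ledger_attempt_counts_match_pipeline():
    cfg = CohortConfig(n_respondents=150, seed=9)
    records, ledger = generate_cohort(cfg)
    groups = {g.ip_key: g.n_attempts for g in group_attempts(records)}
    assert groups == ledger["n_attempts"]


def test_fraudulent_fraction_drives_duplicate_rate():
    """duplicate_excluded fraction increases with repeater prevalence."""
    fracs, ps = [], []
    for seed in range(20):
        for p in (0.1, 0.3):
            cfg = CohortConfig(
                n_respondents=150,
                archetype_mixture={
                    "conscientious": 0.9 - p,
                    "fraudulent_repeater": p,
                    "inattentive": 0.1,
                },
                seed=seed,
            )
            records, _ = generate_cohort(cfg)
            classes = {}
            for g in group_attempts(records):
                classes.update(classify_eligibility(g, qualifies_study1))
            frac = sum(
                1 for c in classes.values() if c == "duplicate_excluded"
            ) / len(records)
            fracs.append(frac)
            ps.append(p)
    rho, _ = spearmanr(ps, fracs)
    assert rho > 0
    low = np.mean([f for f, p in zip(fracs, ps) if p == 0.1])
    high = np.mean([f for f, p in zip(fracs, ps) if p == 0.3])
    assert high > low


def test_study1_replica_determinism_and_ledger(study1):
    from surveyvet import study1_replica

    records, ledger = study1
    again, _ = study1_replica(seed=11)
    assert [r.ip_key for r in records] == [r.ip_key for r in again]
    assert [r.start_time for r in records] == [r.start_time for r in again]
    summary = screening_summary(records)
    assert summary.acceptable == ledger["acceptable"]
    assert summary.attempt_histogram == ledger["attempt_histogram"]
    assert summary.naive_qualified_responses == ledger["naive_qualified_responses"]


def test_study1_diabetes_type_composition(study1):
    records, ledger = study1
    classes = {}
    for g in group_attempts(records):
        classes.update(classify_eligibility(g, qualifies_study1))
    accepted = [r for r in records if classes[r.response_id] == "acceptable"]
    types = [r.answers["diabetes_type"] for r in accepted]
    assert types.count("type1") == 61
    assert types.count("type2") == 146
    assert types.count("dont_know") == 11
    assert types.count("no_diabetes") == 3
    assert types.count(None) == 31


def test_study2_demographic_cells(study2):
    records, _ = study2
    mturk = [r for r in records if r.sample_label == "mturk"]
    ug = [r for r in records if r.sample_label == "undergraduate"]
    assert (len(mturk), len(ug)) == (316, 300)

    def count(sample, item, value):
        return sum(1 for r in sample if r.answers[item] == value)

    assert count(mturk, "sex", "male") == 138
    assert count(mturk, "sex", "female") == 176
    assert count(mturk, "sex", None) == 2
    assert count(ug, "sex", "male") == 67
    assert count(ug, "sex", "female") == 232
    assert count(ug, "sex", None) == 1
    assert count(mturk, "marital", "married_partnered") == 115
    assert count(ug, "marital", "single") == 291
    assert count(mturk, "education", "bachelors") == 114


def test_study2_ages_and_missingness(study2):
    records, _ = study2
    mt = [float(r.answers["age"]) for r in records
          if r.sample_label == "mturk" and r.answers["age"] is not None]
    ug = [float(r.answers["age"]) for r in records
          if r.sample_label == "undergraduate" and r.answers["age"] is not None]
    # 16 blanked ages give the conventional pooled-t df of 598
    assert len(mt) + len(ug) - 2 == 598
    assert np.mean(mt) == pytest.approx(37.67, abs=1.5)
    assert np.mean(ug) == pytest.approx(19.37, abs=1.0)
    assert min(mt) >= 20 and max(mt) <= 69
    assert min(ug) >= 17 and max(ug) <= 62


def test_study2_pooled_time_moments(study2):
    from surveyvet import completion_stats

    records, ledger = study2
    stats = completion_stats([r.completion_seconds for r in records])
    assert stats.mean_seconds == pytest.approx(339.0, abs=5.0)
    assert stats.sd_seconds == pytest.approx(262.0, abs=10.0)
    assert stats.min_seconds == 84  # 1 min 24 s
    assert stats.max_seconds == 4740  # 1 h 19 min


def test_study2_scoring_recovers_planted_table_for_any_seed():
    """Pinned category counts reproduce exactly under a fresh seed."""
    from collections import Counter
    from surveyvet import study2_replica

    records, ledger = study2_replica(seed=303)
    specs = study2_trapspecs()
    times = [r.completion_seconds for r in records]
    flags, _ = timing_flags(times, TimingRule(floor_seconds=120.0, k=3.0))
    totals = Counter()
    for rec, flag in zip(records, flags):
        score = score_respondent(specs, rec, timing_flag=flag)
        totals[rec.sample_label] += score.n_failures
    assert totals["mturk"] == 41
    assert totals["undergraduate"] == 19
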