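import pytest

from surveyvet import (
    TimingRule,
    score_respondent,
    study1_replica,
    study2_replica,
    study2_trapspecs,
    timing_flags,
)


@pytest.fixture(scope="session")
def study1():
    """Replica of the 4165-response qualification-gated survey log."""
    return study1_replica(seed=11)


@pytest.fixture(scope="session")
def study2():
    """Replica of the 616-completer two-sample trap-question study."""
    return study2_replica(seed=7)


@pytest.fixture(scope="session")
def study2_scored(study2):
    """(records, ledger, scores) with timing flags resolved on the cohort."""
    records, ledger = study2
    specs = study2_trapspecs()
    times = [r.completion_seconds for r in records]
    flags, rule = timing_flags(times, TimingRule(floor_seconds=120.0, k=3.0))
    scores = [
        score_respondent(specs, rec, timing_flag=flag)
        for rec, flag in zip(records, flags)
    ]
    return records, ledger, scores, rule
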