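"""Duplicate-IP screening: the exclusion cascade for repeat survey attempts.

The screen groups attempts by hashed IP, excludes *every* response from a
repeat IP (no "keep the first attempt" salvage), classifies single attempts
by a qualification predicate, and detects qualification-status transitions —
respondents who re-attempt the qualification page until they "develop" the
condition under study, or occasionally flip the other way.

The naive comparison figure counts every response whose qualification page
reports the condition, ignoring duplication entirely: what a screen that
never looked at IP multiplicity would have accepted.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .records import ResponseRecord

__all__ = [
    "ELIGIBILITY_CLASSES",
    "AttemptGroup",
    "QualificationTransition",
    "ScreeningSummary",
    "group_attempts",
    "attempt_histogram",
    "classify_eligibility",
    "transition_events",
    "screening_summary",
    "reports_diabetes",
    "diabetes_status",
    "qualifies_study1",
]

ELIGIBILITY_CLASSES = ("acceptable", "single_nonqualified", "duplicate_excluded")

#: qualification predicate / status helpers for the diabetes-survey setting
def reports_diabetes(record: ResponseRecord) -> bool:
    """Did the qualification page report diabetes? (missing counts as no)"""
    return record.qualification_disease == "diabetes"


def diabetes_status(record: ResponseRecord) -> bool | None:
    """Three-valued diabetes status: None when the page was left blank."""
    if record.qualification_disease is None:
        return None
    return record.qualification_disease == "diabetes"


def qualifies_study1(record: ResponseRecord) -> bool:
    """Inclusion rule of the diabetes survey: diabetes reported and adult."""
    return reports_diabetes(record) and record.qualification_adult is True


@dataclass
class AttemptGroup:
    """All attempts from one hashed IP, ascending by start time.

    Ties in ``start_time`` are broken by ``response_id`` lexicographic order
    so grouping is deterministic under row shuffling of the input table.
    """

    ip_key: str
    attempts: list[ResponseRecord]

    def __post_init__(self) -> None:
        if not self.attempts:
            raise ValueError("an attempt group needs at least one attempt")
        if any(rec.ip_key != self.ip_key for rec in self.attempts):
            raise ValueError(f"group {self.ip_key!r}: mixed ip_key values")
        self.attempts = sorted(
            self.attempts, key=lambda r: (r.start_time, r.response_id)
        )

    @property
    def n_attempts(self) -> int:
        return len(self.attempts)


@dataclass(frozen=True)
class QualificationTransition:
    """First qualification-status flip within one repeat-IP group."""

    ip_key: str
    direction: str  # "acquired_condition" | "lost_condition"
    latency_seconds: float  # start(flip attempt) − start(previous attempt)

    def __post_init__(self) -> None:
        if self.direction not in ("acquired_condition", "lost_condition"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.latency_seconds < 0:
            raise ValueError("latency must be non-negative")


@dataclass
class ScreeningSummary:
    """The auditable exclusion ledger of the duplicate-IP screen."""

    total_responses: int
    single_attempt_nonqualified: int
    acceptable: int
    duplicate_responses: int
    duplicate_ips: int
    attempt_histogram: dict[int, int] = field(default_factory=dict)
    naive_qualified_responses: int = 0

    @property
    def mean_attempts_per_duplicate_ip(self) -> float:
        if self.duplicate_ips == 0:
            return 0.0
        return self.duplicate_responses / self.duplicate_ips

    def __post_init__(self) -> None:
        parts = (
            self.single_attempt_nonqualified + self.acceptable + self.duplicate_responses
        )
        if parts != self.total_responses:
            raise ValueError(
                f"eligibility classes ({parts}) do not partition "
                f"total_responses ({self.total_responses})"
            )
        if sum(k * v for k, v in self.attempt_histogram.items()) != self.duplicate_responses:
            raise ValueError("attempt histogram does not conserve duplicate responses")
        if sum(self.attempt_histogram.values()) != self.duplicate_ips:
            raise ValueError("attempt histogram does not conserve duplicate IPs")

    def to_dict(self) -> dict:
        return {
            "total_responses": self.total_responses,
            "single_attempt_nonqualified": self.single_attempt_nonqualified,
            "acceptable": self.acceptable,
            "duplicate_responses": self.duplicate_responses,
            "duplicate_ips": self.duplicate_ips,
            "attempt_histogram": {str(k): v for k, v in sorted(self.attempt_histogram.items())},
            "mean_attempts_per_duplicate_ip": round(self.mean_attempts_per_duplicate_ip, 4),
            "naive_qualified_responses": self.naive_qualified_responses,
        }


def group_attempts(table: Iterable[ResponseRecord]) -> list[AttemptGroup]:
    """Partition records into per-IP attempt groups, sorted by ip_key."""
    by_ip: dict[str, list[ResponseRecord]] = defaultdict(list)
    for rec in table:
        by_ip[rec.ip_key].append(rec)
    return [AttemptGroup(ip, recs) for ip, recs in sorted(by_ip.items())]


def attempt_histogram(
    groups: Iterable[AttemptGroup], min_attempts: int = 2
) -> dict[int, int]:
    """Map attempt count → number of IPs, restricted to repeat IPs by default."""
    counts = Counter(
        g.n_attempts for g in groups if g.n_attempts >= min_attempts
    )
    return dict(sorted(counts.items()))


def classify_eligibility(
    group: AttemptGroup, qualifies: Callable[[ResponseRecord], bool]
) -> dict[str, str]:
    """Per-record eligibility class for one group.

    Every response from a repeat IP is duplicate_excluded — none is salvaged.
    A single attempt is acceptable iff it meets the qualification predicate.
    """
    if group.n_attempts >= 2:
        return {rec.response_id: "duplicate_excluded" for rec in group.attempts}
    rec = group.attempts[0]
    cls = "acceptable" if qualifies(rec) else "single_nonqualified"
    return {rec.response_id: cls}


def transition_events(
    group: AttemptGroup,
    status_of: Callable[[ResponseRecord], bool | None] = diabetes_status,
) -> list[QualificationTransition]:
    """Detect the first qualification-status flip in a repeat-IP group.

    ``status_of`` returns True/False, or None when status is unobserved
    (qualification page left blank); unobserved attempts are skipped when
    scanning for the flip.  At most one event is emitted per group — the
    first flip wins — and its latency is measured from the immediately
    preceding attempt to the flipped attempt.
    """
    baseline: bool | None = None
    for i, rec in enumerate(group.attempts):
        status = status_of(rec)
        if status is None:
            continue
        if baseline is None:
            baseline = status
            continue
        if status != baseline:
            direction = "acquired_condition" if status else "lost_condition"
            prev = group.attempts[i - 1]
            return [
                QualificationTransition(
                    ip_key=group.ip_key,
                    direction=direction,
                    latency_seconds=rec.start_time - prev.start_time,
                )
            ]
    return []


def screening_summary(
    table: Sequence[ResponseRecord],
    qualifies: Callable[[ResponseRecord], bool] = qualifies_study1,
    reports_condition: Callable[[ResponseRecord], bool] = reports_diabetes,
) -> ScreeningSummary:
    """Run the full exclusion cascade and return the screening ledger.

    ``reports_condition`` drives the naive comparison count: responses whose
    qualification page reports the condition regardless of IP multiplicity.
    """
    groups = group_attempts(table)
    classes: dict[str, str] = {}
    for g in groups:
        classes.update(classify_eligibility(g, qualifies))
    tallies = Counter(classes.values())
    dup_groups = [g for g in groups if g.n_attempts >= 2]
    return ScreeningSummary(
        total_responses=len(table),
        single_attempt_nonqualified=tallies["single_nonqualified"],
        acceptable=tallies["acceptable"],
        duplicate_responses=sum(g.n_attempts for g in dup_groups),
        duplicate_ips=len(dup_groups),
        attempt_histogram=attempt_histogram(groups),
        naive_qualified_responses=sum(1 for rec in table if reports_condition(rec)),
    )
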