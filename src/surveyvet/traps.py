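"""Trap-question evaluation and failure scoring.

Traps are items embedded in a survey whose answer pattern reveals
non-conscientious responding without blocking survey progress: entering the
wrong current date, affirming a fictitious disease, affirming both members
of a mutually exclusive pair (male + ever-pregnant), contradicting one's own
disease status, or an implausible completion time.

A blank answer never counts as a failure — a blank is ignorance of intent,
not contradiction — so traps whose items are unanswered evaluate to
``not_applicable``.
"""

from __future__ import annotations

import datetime as _dt
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .records import ResponseRecord, TrapSpec

__all__ = [
    "TrapOutcome",
    "TrapScore",
    "evaluate_trap",
    "score_respondent",
    "failure_distribution",
    "opportunity_count",
    "reference_date_of",
]


@dataclass(frozen=True)
class TrapOutcome:
    trap_id: str
    respondent_id: str
    status: str  # "pass" | "fail" | "not_applicable"

    def __post_init__(self) -> None:
        if self.status not in ("pass", "fail", "not_applicable"):
            raise ValueError(f"bad trap status {self.status!r}")


@dataclass(frozen=True)
class TrapScore:
    respondent_id: str
    n_failures: int
    n_opportunities: int
    failed_trap_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "failed_trap_ids", tuple(self.failed_trap_ids))
        if not 0 <= self.n_failures <= self.n_opportunities:
            raise ValueError("n_failures outside [0, n_opportunities]")
        if len(self.failed_trap_ids) != self.n_failures:
            raise ValueError("failed_trap_ids length disagrees with n_failures")


def reference_date_of(record: ResponseRecord) -> _dt.date:
    """UTC calendar date of the session start — the date trap's reference."""
    return _dt.datetime.fromtimestamp(record.start_time, _dt.timezone.utc).date()


def _parse_date(text: str) -> _dt.date | None:
    try:
        return _dt.date.fromisoformat(text.strip())
    except ValueError:
        return None


def _answer(record: ResponseRecord, spec: TrapSpec, idx: int) -> str | None:
    item = spec.item_refs[idx]
    if item not in record.answers:
        raise KeyError(
            f"trap {spec.trap_id!r}: item {item!r} not present in the record's schema"
        )
    return record.answers[item]


def evaluate_trap(
    spec: TrapSpec,
    record: ResponseRecord,
    reference_date: _dt.date | None = None,
    timing_flag: bool = False,
) -> TrapOutcome:
    """Evaluate one trap for one respondent.

    ``reference_date`` anchors the enter-today's-date trap; it defaults to
    the UTC date of the session start.  Respondents span time zones, so the
    date comparison tolerates ±1 calendar day by default (configurable via
    the spec's ``tolerance_days``).  ``timing_flag`` is the respondent's
    completion-time flag from :mod:`surveyvet.timing`.
    """
    rid = record.response_id

    if spec.category == "timing":
        return TrapOutcome(spec.trap_id, rid, "fail" if timing_flag else "pass")

    if spec.category == "fixed_answer":
        answer = _answer(record, spec, 0)
        if answer is None:
            return TrapOutcome(spec.trap_id, rid, "not_applicable")
        if spec.expected.get("use_reference_date"):
            ref = reference_date or reference_date_of(record)
            tolerance = int(spec.expected.get("tolerance_days", 1))
            answered = _parse_date(answer)
            ok = answered is not None and abs((answered - ref).days) <= tolerance
            return TrapOutcome(spec.trap_id, rid, "pass" if ok else "fail")
        ok = answer == spec.expected["value"]
        return TrapOutcome(spec.trap_id, rid, "pass" if ok else "fail")

    if spec.category == "fictitious_item":
        answer = _answer(record, spec, 0)
        if answer is None:
            return TrapOutcome(spec.trap_id, rid, "not_applicable")
        failed = answer == spec.expected["fail_value"]
        return TrapOutcome(spec.trap_id, rid, "fail" if failed else "pass")

    # linked_exclusive / status_consistency: a forbidden answer pair
    first = _answer(record, spec, 0)
    second = _answer(record, spec, 1)
    if first is None or second is None:
        return TrapOutcome(spec.trap_id, rid, "not_applicable")
    forbidden = spec.expected["forbidden"]
    failed = [first, second] == list(forbidden)
    return TrapOutcome(spec.trap_id, rid, "fail" if failed else "pass")


def score_respondent(
    specs: Sequence[TrapSpec],
    record: ResponseRecord,
    reference_date: _dt.date | None = None,
    timing_flag: bool = False,
) -> TrapScore:
    """Evaluate all traps for one respondent and tally failures.

    Every spec counts as an opportunity, the timing trap included;
    not-applicable outcomes contribute zero failures.
    """
    outcomes = [
        evaluate_trap(spec, record, reference_date, timing_flag) for spec in specs
    ]
    failed = tuple(o.trap_id for o in outcomes if o.status == "fail")
    return TrapScore(
        respondent_id=record.response_id,
        n_failures=len(failed),
        n_opportunities=len(specs),
        failed_trap_ids=failed,
    )


def failure_distribution(
    scores: Sequence[TrapScore],
    by: Mapping[str, str] | None = None,
) -> dict:
    """Percentage of respondents at each failure count.

    With ``by`` (respondent_id → sample label) the distribution is returned
    per label, keyed by label.  Percentages are rounded to 1 d.p. and sum to
    100 within rounding; keys run from 0 to the maximum observed count so
    intermediate zeros are explicit.
    """
    if not scores:
        raise ValueError("failure_distribution requires at least one score")
    if by is not None:
        out: dict[str, dict[int, float]] = {}
        for label in sorted(set(by.values())):
            subset = [s for s in scores if by.get(s.respondent_id) == label]
            out[label] = failure_distribution(subset)
        return out
    counts = Counter(s.n_failures for s in scores)
    n = len(scores)
    top = max(counts)
    return {k: round(100.0 * counts.get(k, 0) / n, 1) for k in range(top + 1)}


def opportunity_count(specs: Sequence[TrapSpec], n_respondents: int) -> int:
    """Total trap opportunities across a cohort: specs × respondents."""
    return len(specs) * n_respondents
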