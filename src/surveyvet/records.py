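"""Data model and I/O for survey response logs and trap specifications.

A *response log* is one row per survey attempt: opaque respondent and
(hashed) IP identifiers, UTC epoch-second timestamps, the qualification-page
answers, and one column per survey item.  IP addresses are ingested only as
salted hashes (``ip_key``): the screening pipeline needs equality and
time-ordering, never the raw address, and health-survey logs are sensitive.

Missing is distinct from any answer value: an unanswered item loads as
``None``, never as an empty string.  This distinction is load-bearing — the
screening logic treats a blank qualification answer as *unobserved* status,
and the trap engine treats a blank trap item as not-applicable rather than
a failure.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ResponseRecord",
    "SurveySchema",
    "TrapSpec",
    "ResponseLogError",
    "TrapSpecError",
    "DurationParseError",
    "META_COLUMNS",
    "TRAP_CATEGORIES",
    "load_responses",
    "write_responses",
    "load_trapspecs",
    "write_trapspecs",
    "parse_duration",
    "format_duration",
]

#: Fixed metadata columns of the canonical response-log CSV, in order.
META_COLUMNS = (
    "response_id",
    "ip_key",
    "start_time",
    "end_time",
    "sample_label",
    "alert_assigned",
    "qualification_disease",
    "qualification_adult",
)

QUALIFICATION_DISEASES = frozenset(
    {"diabetes", "heart_disease", "asthma", "osteoporosis", "none"}
)

TRAP_CATEGORIES = (
    "fixed_answer",
    "fictitious_item",
    "linked_exclusive",
    "status_consistency",
    "timing",
)

#: Number of item references each trap category requires.
_TRAP_ARITY = {
    "fixed_answer": 1,
    "fictitious_item": 1,
    "linked_exclusive": 2,
    "status_consistency": 2,
    "timing": 0,
}


class ResponseLogError(ValueError):
    """Malformed response-log content (bad timestamp, duplicate id, ...)."""


class TrapSpecError(ValueError):
    """Malformed trap specification (unknown category, arity violation)."""


class DurationParseError(ValueError):
    """Unrecognized token in a human-readable duration string."""


@dataclass
class ResponseRecord:
    """One survey attempt.

    ``start_time``/``end_time`` are UTC epoch seconds.  Absolute timezone is
    irrelevant to every duration-based rule; it matters only for the
    current-date trap, which is evaluated against the UTC calendar date of
    ``start_time``.
    """

    response_id: str
    ip_key: str
    start_time: int
    end_time: int
    qualification_disease: str | None = None
    qualification_adult: bool | None = None
    answers: dict[str, str | None] = field(default_factory=dict)
    sample_label: str | None = None
    alert_assigned: bool | None = None

    def __post_init__(self) -> None:
        if self.end_time < self.start_time:
            raise ResponseLogError(
                f"response {self.response_id!r}: end_time {self.end_time} "
                f"precedes start_time {self.start_time}"
            )
        if (
            self.qualification_disease is not None
            and self.qualification_disease not in QUALIFICATION_DISEASES
        ):
            raise ResponseLogError(
                f"response {self.response_id!r}: unknown qualification disease "
                f"{self.qualification_disease!r}"
            )

    @property
    def completion_seconds(self) -> int:
        """Whole-attempt duration in seconds (never negative)."""
        return self.end_time - self.start_time


@dataclass(frozen=True)
class SurveySchema:
    """Ordered item inventory of one survey instrument."""

    item_ids: tuple[str, ...]
    item_types: Mapping[str, str] = field(default_factory=dict)
    required_items: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        object.__setattr__(self, "required_items", frozenset(self.required_items))
        missing = self.required_items - set(self.item_ids)
        if missing:
            raise ValueError(f"required items not in schema: {sorted(missing)}")


@dataclass(frozen=True)
class TrapSpec:
    """Declarative definition of one conscientiousness trap.

    Categories:

    ``fixed_answer``
        One item with a known correct value.  ``expected`` carries either
        ``{"value": ...}`` (exact match required) or
        ``{"use_reference_date": true, "tolerance_days": 1}`` for the
        enter-today's-date trap, which passes within the tolerance window.
    ``fictitious_item``
        One item referencing a nonexistent entity (e.g. the invented disease
        "hyperemblyopia"); ``expected = {"fail_value": ...}``, affirming it
        fails.
    ``linked_exclusive``
        Two items whose answers are mutually exclusive (male + ever-pregnant);
        ``expected = {"forbidden": [v1, v2]}``, giving both fails.
    ``status_consistency``
        Two self-status items that can contradict (diabetes yes-then-no, or
        both diabetes types affirmed); same ``forbidden`` payload.
    ``timing``
        No items; fails when the respondent's completion-time flag is set.
    """

    trap_id: str
    category: str
    item_refs: tuple[str, ...] = ()
    expected: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "item_refs", tuple(self.item_refs))
        if self.category not in _TRAP_ARITY:
            raise TrapSpecError(
                f"trap {self.trap_id!r}: unknown category {self.category!r}"
            )
        arity = _TRAP_ARITY[self.category]
        if len(self.item_refs) != arity:
            raise TrapSpecError(
                f"trap {self.trap_id!r}: category {self.category!r} requires "
                f"{arity} item reference(s), got {len(self.item_refs)}"
            )


# ---------------------------------------------------------------------------
# response-log CSV I/O


def _parse_bool(text: str, row: int, column: str) -> bool:
    if text == "true":
        return True
    if text == "false":
        return False
    raise ResponseLogError(f"row {row}: column {column!r}: bad boolean {text!r}")


def _parse_timestamp(text: str, row: int, column: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise ResponseLogError(
            f"row {row}: column {column!r}: malformed timestamp {text!r}"
        ) from None


def load_responses(path: str | Path, schema: SurveySchema) -> list[ResponseRecord]:
    """Read a canonical response-log CSV into validated records.

    The header must be the fixed metadata columns followed by exactly the
    schema's item ids, in order.  Empty cells become ``None`` (missing),
    never empty-string answers.  Row indices in error messages are 1-based
    data rows (the header is row 0).
    """
    path = Path(path)
    expected_header = list(META_COLUMNS) + list(schema.item_ids)
    records: list[ResponseRecord] = []
    seen_ids: set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ResponseLogError(f"{path}: empty file, header required") from None
        if header != expected_header:
            raise ResponseLogError(
                f"{path}: header mismatch; expected {expected_header}, got {header}"
            )
        for i, row in enumerate(reader, start=1):
            if len(row) != len(expected_header):
                raise ResponseLogError(
                    f"row {i}: expected {len(expected_header)} cells, got {len(row)}"
                )
            cells = dict(zip(expected_header, row))
            rid = cells["response_id"]
            if rid in seen_ids:
                raise ResponseLogError(f"row {i}: duplicate response_id {rid!r}")
            seen_ids.add(rid)
            answers = {
                item: (cells[item] if cells[item] != "" else None)
                for item in schema.item_ids
            }
            records.append(
                ResponseRecord(
                    response_id=rid,
                    ip_key=cells["ip_key"],
                    start_time=_parse_timestamp(cells["start_time"], i, "start_time"),
                    end_time=_parse_timestamp(cells["end_time"], i, "end_time"),
                    sample_label=cells["sample_label"] or None,
                    alert_assigned=(
                        _parse_bool(cells["alert_assigned"], i, "alert_assigned")
                        if cells["alert_assigned"]
                        else None
                    ),
                    qualification_disease=cells["qualification_disease"] or None,
                    qualification_adult=(
                        _parse_bool(
                            cells["qualification_adult"], i, "qualification_adult"
                        )
                        if cells["qualification_adult"]
                        else None
                    ),
                    answers=answers,
                )
            )
    return records


def _format_cell(value: object) -> str:
    if value is None:
        return ""
    if value is True:
        return "true"
    if value is False:
        return "false"
    return str(value)


def write_responses(
    path: str | Path, records: Iterable[ResponseRecord], schema: SurveySchema
) -> None:
    """Write records as the canonical comma-separated, UTF-8, RFC-4180 log."""
    path = Path(path)
    header = list(META_COLUMNS) + list(schema.item_ids)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec in records:
            row = [
                rec.response_id,
                rec.ip_key,
                str(rec.start_time),
                str(rec.end_time),
                _format_cell(rec.sample_label),
                _format_cell(rec.alert_assigned),
                _format_cell(rec.qualification_disease),
                _format_cell(rec.qualification_adult),
            ]
            row.extend(_format_cell(rec.answers.get(item)) for item in schema.item_ids)
            writer.writerow(row)


# ---------------------------------------------------------------------------
# trap-spec JSON I/O


def load_trapspecs(path: str | Path) -> list[TrapSpec]:
    """Read a JSON array of trap definitions, validating category arity."""
    with Path(path).open(encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise TrapSpecError("trap-spec file must contain a JSON array")
    specs = [
        TrapSpec(
            trap_id=obj["trap_id"],
            category=obj["category"],
            item_refs=tuple(obj.get("item_refs", ())),
            expected=obj.get("expected", {}),
        )
        for obj in raw
    ]
    ids = [s.trap_id for s in specs]
    if len(set(ids)) != len(ids):
        dupes = sorted({t for t in ids if ids.count(t) > 1})
        raise TrapSpecError(f"duplicate trap_id(s): {dupes}")
    return specs


def write_trapspecs(path: str | Path, specs: Sequence[TrapSpec]) -> None:
    payload = [
        {
            "trap_id": s.trap_id,
            "category": s.category,
            "item_refs": list(s.item_refs),
            "expected": dict(s.expected),
        }
        for s in specs
    ]
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


# ---------------------------------------------------------------------------
# human-readable durations ("4 h 45 min", "8 s")

_DURATION_TOKEN = re.compile(r"(\d+)\s*(h|min|s)\b")
_UNIT_SECONDS = {"h": 3600, "min": 60, "s": 1}


def parse_duration(text: str) -> int:
    """Parse ``"Nh Nmin Ns"`` (any subset of components) to integer seconds.

    >>> parse_duration("4 h 45 min")
    17100
    """
    total = 0
    pos = 0
    matched_any = False
    for m in _DURATION_TOKEN.finditer(text):
        leftover = text[pos : m.start()].strip()
        if leftover:
            raise DurationParseError(f"unrecognized token {leftover!r} in {text!r}")
        total += int(m.group(1)) * _UNIT_SECONDS[m.group(2)]
        matched_any = True
        pos = m.end()
    leftover = text[pos:].strip()
    if leftover or not matched_any:
        raise DurationParseError(
            f"unrecognized token {leftover or text.strip()!r} in {text!r}"
        )
    return total


def format_duration(seconds: int) -> str:
    """Inverse of :func:`parse_duration` on canonical formatting."""
    if seconds < 0:
        raise ValueError("duration must be non-negative")
    h, rem = divmod(int(seconds), 3600)
    m, s = divmod(rem, 60)
    parts = []
    if h:
        parts.append(f"{h} h")
    if m:
        parts.append(f"{m} min")
    if s or not parts:
        parts.append(f"{s} s")
    return " ".join(parts)
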