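"""Publication-ready quality report for a screened response log.

The report carries the fields a journal reviewer needs to audit a
web-survey screen: the exclusion ledger (every removed response attributed
to exactly one rule, in the fixed order duplicate-IP → qualification →
timing → trap-based), completion-time statistics and rule parameters, the
trap inventory and failure tables, and free-form platform metadata
(qualification filters, incentive, hosting settings).
"""

from __future__ import annotations

import csv
import datetime as _dt
from pathlib import Path
from typing import Callable, Mapping, Sequence

from .dedup import (
    group_attempts,
    classify_eligibility,
    transition_events,
    screening_summary,
    qualifies_study1,
    reports_diabetes,
    diabetes_status,
)
from .records import ResponseRecord, TrapSpec
from .timing import TimingRule, completion_stats, timing_flags
from .traps import failure_distribution, score_respondent, opportunity_count

__all__ = ["build_quality_report", "render_report_markdown", "write_report_files"]

_RULE_ORDER = ("duplicate_ip", "qualification", "timing", "trap")


def build_quality_report(
    table: Sequence[ResponseRecord],
    trapspecs: Sequence[TrapSpec] = (),
    qualifies: Callable[[ResponseRecord], bool] = qualifies_study1,
    timing_rule: TimingRule | None = None,
    max_trap_failures: int | None = None,
    metadata: Mapping[str, object] | None = None,
) -> dict:
    """Screen a response log end-to-end and assemble the quality report.

    Exclusion attribution is first-matching-rule-wins in the order
    duplicate-IP, qualification, timing, trap-based; the per-rule counts
    plus the retained count always sum to the input rows.
    ``max_trap_failures`` (when trap specs are supplied) excludes
    respondents failing strictly more than that many traps; ``None`` means
    traps are reported but exclude nobody.
    """
    if not table:
        raise ValueError("empty response table")
    rule = timing_rule or TimingRule(floor_seconds=120.0, k=3.0)

    summary = screening_summary(table, qualifies)
    groups = group_attempts(table)
    eligibility: dict[str, str] = {}
    for g in groups:
        eligibility.update(classify_eligibility(g, qualifies))
    transitions = [
        ev for g in groups if g.n_attempts >= 2 for ev in transition_events(g, diabetes_status)
    ]

    times = [rec.completion_seconds for rec in table]
    stats = completion_stats(times)
    flags, resolved_rule = timing_flags(times, rule)
    flag_by_id = {rec.response_id: f for rec, f in zip(table, flags)}

    scores = []
    if trapspecs:
        for rec in table:
            scores.append(
                score_respondent(
                    trapspecs, rec, timing_flag=flag_by_id[rec.response_id]
                )
            )
    score_by_id = {s.respondent_id: s for s in scores}

    exclusions: dict[str, str] = {}  # response_id -> rule
    for rec in table:
        rid = rec.response_id
        if eligibility[rid] == "duplicate_excluded":
            exclusions[rid] = "duplicate_ip"
        elif eligibility[rid] == "single_nonqualified":
            exclusions[rid] = "qualification"
        elif flag_by_id[rid]:
            exclusions[rid] = "timing"
        elif (
            max_trap_failures is not None
            and rid in score_by_id
            and score_by_id[rid].n_failures > max_trap_failures
        ):
            exclusions[rid] = "trap"
    retained = len(table) - len(exclusions)

    trap_section: dict = {"n_specs": len(trapspecs)}
    if scores:
        by_sample = {
            rec.response_id: rec.sample_label or "all" for rec in table
        }
        trap_section.update(
            {
                "opportunities": opportunity_count(trapspecs, len(table)),
                "total_failures": sum(s.n_failures for s in scores),
                "failure_distribution": failure_distribution(scores),
                "failure_distribution_by_sample": failure_distribution(
                    scores, by=by_sample
                ),
            }
        )

    report = {
        "generated_utc": _dt.datetime.now(_dt.timezone.utc).isoformat(
            timespec="seconds"
        ),
        "screening": summary.to_dict(),
        "transitions": {
            "acquired_condition": sum(
                1 for t in transitions if t.direction == "acquired_condition"
            ),
            "acquired_within_60s": sum(
                1
                for t in transitions
                if t.direction == "acquired_condition" and t.latency_seconds <= 60
            ),
            "lost_condition": sum(
                1 for t in transitions if t.direction == "lost_condition"
            ),
        },
        "timing": {
            "mean_seconds": round(stats.mean_seconds, 2),
            "sd_seconds": round(stats.sd_seconds, 2),
            "min_seconds": stats.min_seconds,
            "max_seconds": stats.max_seconds,
            "floor_seconds": resolved_rule.floor_seconds,
            "k": resolved_rule.k,
            "ceiling_seconds": resolved_rule.computed_ceiling_seconds,
            "n_flagged": sum(flags),
        },
        "traps": trap_section,
        "exclusion_ledger": {
            "input_rows": len(table),
            "excluded_by_rule": {
                r: sum(1 for v in exclusions.values() if v == r) for r in _RULE_ORDER
            },
            "retained": retained,
        },
        "metadata": dict(metadata or {}),
        "_per_response": {
            rec.response_id: {
                "eligibility_class": eligibility[rec.response_id],
                "timing_flagged": flag_by_id[rec.response_id],
                "excluded_by": exclusions.get(rec.response_id),
                "n_trap_failures": (
                    score_by_id[rec.response_id].n_failures
                    if rec.response_id in score_by_id
                    else None
                ),
            }
            for rec in table
        },
    }
    ledger = report["exclusion_ledger"]
    assert sum(ledger["excluded_by_rule"].values()) + ledger["retained"] == len(table)
    return report


def render_report_markdown(report: dict) -> str:
    """Human-readable rendering of a quality report."""
    s = report["screening"]
    t = report["timing"]
    lines = [
        "# Survey quality report",
        "",
        "## Duplicate-IP screening",
        "",
        f"- total responses: {s['total_responses']}",
        f"- single-attempt, non-qualified: {s['single_attempt_nonqualified']}",
        f"- acceptable (single attempt, qualified): {s['acceptable']}",
        f"- responses from repeat IPs (all excluded): {s['duplicate_responses']} "
        f"from {s['duplicate_ips']} IPs "
        f"(mean {s['mean_attempts_per_duplicate_ip']:.2f} attempts)",
        f"- naive qualification-page-only screen would accept: "
        f"{s['naive_qualified_responses']}",
        "",
        "attempts per repeat IP: "
        + ", ".join(f"{k}×{v}" for k, v in s["attempt_histogram"].items()),
        "",
        "## Qualification-status transitions (repeat IPs)",
        "",
        f"- acquired the condition: {report['transitions']['acquired_condition']} "
        f"(within 60 s: {report['transitions']['acquired_within_60s']})",
        f"- lost the condition: {report['transitions']['lost_condition']}",
        "",
        "## Completion times",
        "",
        f"- mean {t['mean_seconds']} s, SD {t['sd_seconds']} s, "
        f"range {t['min_seconds']}–{t['max_seconds']} s",
        f"- floor {t['floor_seconds']} s"
        + (
            f", ceiling mean+{t['k']}·SD = {t['ceiling_seconds']:.0f} s"
            if t["ceiling_seconds"] is not None
            else " (no ceiling)"
        ),
        f"- flagged: {t['n_flagged']}",
        "",
        "## Traps",
        "",
    ]
    traps = report["traps"]
    if traps.get("opportunities"):
        lines += [
            f"- {traps['n_specs']} traps × {report['exclusion_ledger']['input_rows']} "
            f"respondents = {traps['opportunities']} opportunities",
            f"- total failures: {traps['total_failures']}",
            "- failure distribution (%): "
            + ", ".join(
                f"{k}: {v}" for k, v in traps["failure_distribution"].items()
            ),
        ]
    else:
        lines.append("- no trap specifications supplied")
    ledger = report["exclusion_ledger"]
    lines += [
        "",
        "## Exclusion ledger",
        "",
        f"- input rows: {ledger['input_rows']}",
    ]
    lines += [
        f"- excluded by {rule}: {n}"
        for rule, n in ledger["excluded_by_rule"].items()
    ]
    lines.append(f"- retained: {ledger['retained']}")
    if report["metadata"]:
        lines += ["", "## Platform and filter metadata", ""]
        lines += [f"- {k}: {v}" for k, v in report["metadata"].items()]
    return "\n".join(lines) + "\n"


def write_report_files(report: dict, out_dir: str | Path) -> None:
    """Write report.json, report.md and the per-response eligibility CSV."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    per_response = report.pop("_per_response")
    (out / "report.json").write_text(
        json.dumps(report, indent=1, default=str), encoding="utf-8"
    )
    (out / "report.md").write_text(render_report_markdown(report), encoding="utf-8")
    with (out / "eligibility.csv").open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["response_id", "eligibility_class", "timing_flagged", "excluded_by",
             "n_trap_failures"]
        )
        for rid, row in per_response.items():
            writer.writerow(
                [
                    rid,
                    row["eligibility_class"],
                    "true" if row["timing_flagged"] else "false",
                    row["excluded_by"] or "",
                    "" if row["n_trap_failures"] is None else row["n_trap_failures"],
                ]
            )
    report["_per_response"] = per_response
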