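"""Completion-time statistics and screening rules.

Two rules are supported.  A fixed floor screens out implausibly fast
completions ("less than 5 min" on a 25-minute instrument; "less than 2 min"
on a 10-minute one).  A ceiling at ``mean + k·SD`` of the cohort's own
completion times screens out implausibly slow ones.  Both comparisons are
strict — a time exactly at the floor or the ceiling is not flagged — and no
symmetric ``mean − k·SD`` lower rule exists: with the dispersions typical of
web surveys it would admit a completion time of 0 s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

__all__ = ["TimingStats", "TimingRule", "completion_stats", "timing_flags"]


@dataclass(frozen=True)
class TimingStats:
    """Sample moments of a cohort's completion times (seconds)."""

    mean_seconds: float
    sd_seconds: float  # sample SD, n−1 denominator
    min_seconds: float
    max_seconds: float
    n: int


@dataclass(frozen=True)
class TimingRule:
    """Floor/ceiling screening rule.

    ``k is None`` disables the ceiling (pure floor screen).  The ceiling is
    resolved against a cohort's :class:`TimingStats`; once resolved,
    ``computed_ceiling_seconds = mean + k·sd``.
    """

    floor_seconds: float = 120.0
    k: float | None = 3.0
    computed_ceiling_seconds: float | None = None

    def resolve(self, stats: TimingStats) -> "TimingRule":
        if self.k is None:
            return replace(self, computed_ceiling_seconds=None)
        ceiling = stats.mean_seconds + self.k * stats.sd_seconds
        if ceiling <= self.floor_seconds:
            raise ValueError(
                f"degenerate rule: ceiling {ceiling:.1f} s is not above the "
                f"floor {self.floor_seconds:.1f} s"
            )
        return replace(self, computed_ceiling_seconds=ceiling)


def completion_stats(times: Sequence[float]) -> TimingStats:
    """Mean/SD/range of completion times; SD uses the n−1 denominator."""
    if len(times) == 0:
        raise ValueError("completion_stats requires a non-empty sample")
    if min(times) < 0:
        raise ValueError("completion times must be non-negative")
    n = len(times)
    mean = math.fsum(times) / n
    if n == 1:
        sd = 0.0
    else:
        sd = math.sqrt(math.fsum((t - mean) ** 2 for t in times) / (n - 1))
    return TimingStats(
        mean_seconds=mean,
        sd_seconds=sd,
        min_seconds=min(times),
        max_seconds=max(times),
        n=n,
    )


def timing_flags(
    times: Sequence[float], rule: TimingRule
) -> tuple[list[bool], TimingRule]:
    """Flag each time under the rule; returns (flags, resolved rule).

    The ceiling is computed from the supplied cohort's own moments unless the
    rule already carries a resolved ceiling.  Both boundaries are strict:
    ``flag = (t < floor) or (t > ceiling)``.
    """
    if rule.k is not None and rule.computed_ceiling_seconds is None:
        rule = rule.resolve(completion_stats(times))
    ceiling = rule.computed_ceiling_seconds
    flags = [
        (t < rule.floor_seconds) or (ceiling is not None and t > ceiling)
        for t in times
    ]
    return flags, rule
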