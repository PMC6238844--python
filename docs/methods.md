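# Methods

## The problem

Web-collected health-survey data is vulnerable to a handful of well-known
failure modes: respondents re-attempting a qualification page from the same
IP until it admits them ("acquiring" the disease under study within
seconds), automated form-fillers completing a 25-minute instrument in
seconds, and inattentive respondents contradicting their own answers.
`surveyvet` implements the screening procedures that detect these behaviors
on a response log, the statistics conventionally published alongside such
screens, and a generative model of respondent behavior that makes every
stage testable without access to any real log.

## Screening model

**Duplicate-IP cascade.** Attempts are grouped by a salted hash of the IP
(`ip_key`); raw addresses are never ingested. Every response from an IP with
two or more attempts is excluded — no "keep the first attempt" salvage —
because a re-attempting respondent's earlier and later answers are equally
untrustworthy. Single attempts are then split by a caller-supplied
qualification predicate into `acceptable` and `single_nonqualified`. The
three classes partition the table for every input, and the summary is
invariant under row shuffling (ties in `start_time` are broken by
`response_id`). The ledger also reports the *naive* count: responses whose
qualification page reports the condition regardless of multiplicity, i.e.
what a screen that never looked at IPs would have accepted.

**Qualification transitions.** Within a repeat-IP group, attempts are
scanned in time order with a three-valued status (condition reported /
not reported / page left blank). Blank-status attempts are skipped: a blank
tells us nothing about what the respondent would have claimed, so it can
anchor neither direction of a flip. The first observed flip wins and is the
group's single event; its latency is the start-time gap from the immediately
preceding attempt. This convention means a group can report the condition in
some attempt yet emit no event (blank first, condition thereafter), which is
exactly the behavior needed to make the replica's printed margins
(277 condition-reporting repeat IPs; 210 + 13 flip events; 307 duplicate
condition-positive responses) simultaneously consistent.

**Timing rules.** Completion time is `end_time − start_time`; in the
two-sample study fixtures `start_time` is the post-alert clock start, so
this difference is precisely the duration the published rules consume. Two
rules are supported: a fixed floor (300 s for the 25-minute instrument,
120 s for the 10-minute one) and a ceiling at `mean + k·SD` (k = 3) of the
cohort's own times, with the sample (n−1) standard deviation. Both
comparisons are strict — a time exactly at a boundary is not flagged — and
there is deliberately no symmetric lower `mean − k·SD` rule, which for these
dispersions would admit a completion time of 0 s.

**Traps.** A trap is a declarative spec: a fixed-answer item (the
enter-today's-date question), a fictitious item whose affirmation fails, a
forbidden answer pair across two items (mutually exclusive experiences, or
self-status contradictions), or the timing flag. A blank answer on any
referenced item yields `not_applicable`, never a failure: a blank is
ignorance of intent, not contradiction. The date trap compares against the
UTC calendar date of the session start with a ±1-day tolerance, since
respondents span time zones; an unparseable date string fails (entering
garbage where a date was requested is itself non-conscientious). The
packaged inventory has 26 opportunities: 1 date + 9 fictitious + 13
sex-linked + 2 diabetes-consistency question traps plus the timing trap
(26 × 616 respondents = 16,016 potential failures).

## Inferential layer

Conventions mirror SPSS-style reporting, which is what the surrounding
literature prints and what the package's outputs are compared against:

- **Pearson chi-square** without continuity correction, after dropping
  non-substantive categories ("did not specify") from the table.
- **Factorial ANOVA**: fixed-effects between-subjects model, Type-III sums
  of squares under sum-to-zero (effects) coding, listwise deletion. The
  default model is the full factorial (the SPSS UNIANOVA default);
  `include_interactions=False` fits main effects only. For *replica* data
  the main-effects model is the right analysis: the generator plants
  failures independently of sex and of the alert arm beyond the pinned
  totals, so interaction terms estimate pure noise and only dilute the
  planted main effects.
- **Partial eta-squared** is recovered from F via
  η²ₚ = F·df1 / (F·df1 + df2); this identity reproduces the printed .004,
  .007 and .027 exactly, confirming the printed effect sizes are partial.
- **Observed power** is the noncentral-F tail beyond the central critical
  value at α = .05 with noncentrality λ = F·df1. This convention reproduces
  all five printed (F, power) pairs to 2 d.p. At F = 0 the definition
  degenerates to α.
- **Two-sample t**: pooled-variance Student t, df = n₁ + n₂ − 2, complete
  cases.

## The synthetic-data generator

`generate_cohort` draws respondents from a mixture of four archetypes —
conscientious, speeder bot, fraudulent repeater, inattentive — each with a
log-normal completion-time distribution, a re-attempt probability with a
fast/slow latency mixture, a qualification-gaming probability, and a
per-trap compliance probability. The generator emits a ledger (true
archetype, attempt count per respondent) so pipeline statistics can be
checked against the generator's own bookkeeping, and so parameter-recovery
properties (duplicate-excluded fraction increasing in the repeater
proportion) can be asserted across seeds.

`study1_replica` and `study2_replica` pin the exact compositions of the two
motivating datasets; counts are assigned deterministically and only
timestamps, assignment of planted behaviors to individuals, and free answer
fields vary with the seed. Pinned study-1 composition: 4165 responses =
2667 single non-qualified + 252 single qualifiers + 1246 responses from 533
repeat IPs (histogram 2:400, 3:101, 4:19, 5:11, 6:2). Repeat-IP behavior:
256 groups never report the condition; 210 flip to it on their final
attempt (185 with latency ≤ 60 s drawn uniform(5, 60), 25 slower,
61 s + log-normal); 13 start positive and flip away (latencies recentred to
mean exactly 12,852 s ≈ 3.57 h); 54 leave the first qualification blank and
report the condition thereafter (24 of size 2, 30 of size 3), contributing
the 84 responses that bring duplicate condition-positive responses to 307
and the naive screen to 559. Among the 252 qualifiers, the
later-in-survey diabetes-type answers split 61/146/11/3 with 31 blank, and
exactly 49 complete under 300 s (including the printed 8-s minimum; maximum
17,100 s).

Pinned study-2 composition: 316 + 300 completers with demographic cells set
to the printed table (the crowdsourced race column prints 315 of 316; the
leftover respondent gets a blank). Sixty trap failures are planted to
satisfy the per-category totals (date 19/10, fictitious 0/2, sex 7/2 — with
the 7 realized as three single and two double failers — diabetes 2/0,
timing 13/5) and the per-person counts (278/35/3/0 and 285/12/2/1 at 0–3
failures) simultaneously; both margins were solved arithmetically from the
printed percentage table before implementation. The alert arm is exactly
half of each sample and carries 24 of the 60 failures (means .078 vs .117),
mirroring the published direction at non-significant strength. Completion
times place 18 outliers (fast < 120 s including the 84-s minimum; slow
> 1125 s including the 4740-s maximum) on the timing-failure persons and
draw the remaining 598 from shifted log-normals (crowdsourced faster), then
affinely moment-match the pooled sample to mean 339 s and SD 262 s exactly,
so the mean + 3·SD ceiling lands at exactly 1125 s (18 min 45 s). Ages are
truncated shifted gammas matched to the printed moments and ranges, with 16
blanked so the pooled age-t has its conventional df of 598. Vignette
ratings are drawn around the printed cell means (1–5 Likert, SD 0.85,
clipped), which preserves the large cause main effect though clipping
shifts the genetic-cause cell means upward somewhat.

### What the replicas do and do not show

Replica fixtures demonstrate that the pipeline *recovers planted structure
exactly*: counts, histograms, transitions, failure tables, moments. They do
not validate behavioral realism — real re-attempt latencies, the joint
distribution of demographics with trap failures, and the unknown answer
patterns of the 54 no-flip repeat IPs are all modeled by assumption. Real
logs also arrive with platform-specific export quirks the canonical CSV
does not emulate. Statistics of the real datasets that their publication
leaves ambiguous (per-sample mean failures with unexplained denominators,
the race chi-square whose printed column sums are inconsistent) are
deliberately not asserted anywhere; the engine reports raw means and leaves
analysis-subset choices to the caller.

## Numerical choices and degenerate inputs

- SD of a single observation is defined as 0 rather than NaN.
- `failure_distribution` keys run 0..max observed, so intermediate zeros
  are explicit; rounding is to 1 d.p. and row sums are within ±0.2 of 100.
- A timing rule whose resolved ceiling does not exceed its floor raises.
- Chi-square tables with a zero margin raise, naming the degenerate
  row/column; tables smaller than 2×2 after drops raise.
- `anova_between` warns on empty cells in the full design and raises on
  singular (aliased) design matrices; factors with <2 levels after listwise
  deletion raise.
- Durations are integer seconds; `parse_duration`/`format_duration` are
  exact inverses on canonical strings for all values tested (0..10⁶ s).
- Replica generators use a single `numpy` `Generator` seeded from the
  caller; identical seeds give byte-identical CSV output.

## Problem sizes

The packaged replicas are generated at full published scale (4165 and 616
rows) — generation and screening complete in well under a second — so no
scaled-down fixtures are needed anywhere in the test suite. The Monte-Carlo
cross-check of observed power uses 10⁶ draws of the noncentral-F ratio; the
mixture-generator parameter-recovery property uses 40 cohorts of 150
respondents across 20 seeds.

## Known limitations

- The multivariate vignette analysis is exercised as univariate ANOVAs per
  rating; no MANOVA is implemented.
- No cross-IP fingerprinting (cookies, device IDs): an actor rotating IPs
  is invisible to this screen.
- The CSV dialect is a repository convention (RFC-4180, UTF-8, fixed
  metadata columns); platform exports must be mapped to it upstream.
- Trap specs express forbidden *pairs*; traps over three or more mutually
  exclusive items would need decomposition into pairwise specs.
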