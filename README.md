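# surveyvet

Quality assurance for web-based health-survey response logs.

Surveys run on crowdsourcing platforms can be flooded with responses that
look valid row-by-row but are worthless in aggregate: the same IP
re-attempting a qualification page until it reports the disease under study,
bots completing a 25-minute instrument in 8 seconds, respondents who affirm
a fictitious disorder or report being male *and* ever-pregnant. `surveyvet`
is a library (plus a thin CLI) for survey methodologists and health
researchers who need to screen such logs and report the screen auditably:

- **Duplicate-IP screening** — group attempts by hashed IP, exclude every
  repeat-IP response, classify single attempts by a qualification predicate,
  and detect qualification-status transitions ("developed diabetes within
  60 s") with their latencies.
- **Trap-question scoring** — declarative trap specs (fixed-answer date
  checks, fictitious items, mutually exclusive answer pairs, self-status
  contradictions, completion-time flags) evaluated per respondent, with
  failure counts and distributions.
- **Timing rules** — a fixed floor for implausibly fast completions and a
  cohort-relative ceiling at mean + *k*·SD; strict boundaries, no lower
  SD rule.
- **Inferential layer** — Pearson χ² composition tests (no continuity
  correction), Type-III factorial ANOVA with effects coding, partial
  η²ₚ = F·df₁/(F·df₁ + df₂), observed power from the noncentral-F tail with
  λ = F·df₁, and pooled-variance t-tests.
- **Synthetic respondents** — an archetype-mixture generator
  (conscientious / speeder bot / fraudulent repeater / inattentive) and two
  pinned replica cohorts that reproduce the published compositions of a
  4165-response qualification-gated survey and a 616-completer two-sample
  trap-question study, enabling fully offline end-to-end testing.

## Worked example

```python
from surveyvet import (study1_replica, screening_summary, group_attempts,
                       transition_events, diabetes_status)

records, _ = study1_replica(seed=7)      # 4165 synthetic survey attempts
summary = screening_summary(records)
print(summary.to_dict())
```

```
{'total_responses': 4165, 'single_attempt_nonqualified': 2667,
 'acceptable': 252, 'duplicate_responses': 1246, 'duplicate_ips': 533,
 'attempt_histogram': {'2': 400, '3': 101, '4': 19, '5': 11, '6': 2},
 'mean_attempts_per_duplicate_ip': 2.3377, 'naive_qualified_responses': 559}
```

Only 252 of 4165 responses (6.05%) survive the screen: one attempt from
their IP *and* a qualifying answer. A naive screen that trusted the
qualification page would have accepted 559 (13.42%) — more than twice as
many — because 533 IPs attempted the survey two to six times (mean 2.34).
The transition detector shows why those duplicates are untrustworthy:

```python
events = [ev for g in group_attempts(records) if g.n_attempts >= 2
          for ev in transition_events(g, diabetes_status)]
acquired = [e for e in events if e.direction == "acquired_condition"]
print(len(acquired), sum(1 for e in acquired if e.latency_seconds <= 60))
# 210 185   → 210 IPs "developed" diabetes across attempts, 185 within 60 s
```

The `examples/` directory has one short script per capability
(`screen_duplicate_ips.py`, `score_trap_questions.py`,
`factorial_statistics.py`, `simulate_cohort.py`); each builds its input,
runs the method, and prints annotated results. The same pipeline is
available from a shell:

```sh
surveyvet simulate --study 1 --seed 7 --out sim/
surveyvet screen --responses sim/responses.csv --schema study1 --report report/
surveyvet stats --report report/
```

which writes `report.json`, `report.md`, and a per-response
`eligibility.csv` in which every excluded row is attributed to exactly one
rule (duplicate-IP → qualification → timing → trap).

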