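"""Generative model of web-survey respondent behavior.

Two layers:

* :func:`generate_cohort` draws respondents from a mixture of behavioral
  archetypes — conscientious responders, automated speeder bots, fraudulent
  repeaters who re-attempt a qualification page until they "acquire" the
  condition under study, and inattentive-but-honest responders — and emits a
  schema-valid response log plus a generator ledger (the true archetype and
  planted behavior per respondent) for oracle testing.

* :func:`study1_replica` and :func:`study2_replica` pin the exact printed
  compositions of the two motivating datasets: a 4165-response crowdsourced
  health survey dominated by duplicate-IP re-attempts, and a 616-completer
  two-sample trap-question study.  Replica mode pins counts (deterministic
  assignment, then seed-driven shuffling and timestamp jitter) rather than
  sampling, so count-valued statistics reproduce exactly for every seed
  while free fields (timestamps, which respondent carries which planted
  behavior) vary with the seed.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .records import ResponseRecord, SurveySchema, TrapSpec

__all__ = [
    "ArchetypeParams",
    "CohortConfig",
    "ARCHETYPES",
    "generate_cohort",
    "study1_replica",
    "study2_replica",
    "study1_schema",
    "study2_schema",
    "study2_trapspecs",
]

# epoch anchors: arbitrary UTC dates inside the two collection windows
_STUDY1_T0 = 1_459_468_800  # 2016-04-01
_STUDY1_WINDOW = 180 * 86_400  # six months of collection
_STUDY2_T0 = 1_475_280_000  # 2016-10-01
_STUDY2_WINDOW = 15 * 7 * 86_400  # fifteen weeks

_NON_QUALIFYING = ("none", "heart_disease", "asthma", "osteoporosis")


# ---------------------------------------------------------------------------
# schemas and packaged trap specifications


def study1_schema() -> SurveySchema:
    """Items of the 25-minute qualification-gated health survey."""
    return SurveySchema(
        item_ids=("diabetes_type", "age", "sex", "race"),
        item_types={
            "diabetes_type": "categorical",
            "age": "numeric",
            "sex": "categorical",
            "race": "categorical",
        },
    )


_FICT_ITEMS = tuple(f"fict_{i}" for i in range(1, 10))
_SEXTRAP_ITEMS = tuple(f"sextrap_{i}" for i in range(1, 14))


def study2_schema() -> SurveySchema:
    """Items of the 10-minute two-sample trap-question survey."""
    items = (
        ("age", "sex", "race", "marital", "education", "survey_date")
        + _FICT_ITEMS
        + _SEXTRAP_ITEMS
        + (
            "has_diabetes",
            "has_diabetes_confirm",
            "dx_type1",
            "dx_type2",
            "vignette_cause",
            "vignette_disease",
            "rating_responsibility",
            "rating_anger",
            "rating_blame",
        )
    )
    return SurveySchema(item_ids=items)


def study2_trapspecs() -> list[TrapSpec]:
    """The packaged 26-opportunity trap inventory.

    25 question-based traps (1 current-date, 9 fictitious-disease, 13
    sex-linked exclusive pairs, 2 diabetes-status consistency checks) plus
    the completion-time trap.
    """
    specs: list[TrapSpec] = [
        TrapSpec(
            "date",
            "fixed_answer",
            ("survey_date",),
            {"use_reference_date": True, "tolerance_days": 1},
        )
    ]
    specs += [
        TrapSpec(f"fict_{i}", "fictitious_item", (f"fict_{i}",), {"fail_value": "yes"})
        for i in range(1, 10)
    ]
    # traps 1-7 are female-only experiences (fail pair: male + yes),
    # traps 8-13 male-only (fail pair: female + yes)
    for i in range(1, 14):
        forbidden_sex = "male" if i <= 7 else "female"
        specs.append(
            TrapSpec(
                f"sex_{i}",
                "linked_exclusive",
                ("sex", f"sextrap_{i}"),
                {"forbidden": [forbidden_sex, "yes"]},
            )
        )
    specs.append(
        TrapSpec(
            "diab_status",
            "status_consistency",
            ("has_diabetes", "has_diabetes_confirm"),
            {"forbidden": ["yes", "no"]},
        )
    )
    specs.append(
        TrapSpec(
            "diab_types",
            "status_consistency",
            ("dx_type1", "dx_type2"),
            {"forbidden": ["yes", "yes"]},
        )
    )
    specs.append(TrapSpec("timing", "timing"))
    return specs


# ---------------------------------------------------------------------------
# archetype mixture model


@dataclass(frozen=True)
class ArchetypeParams:
    """Behavioral parameters of one respondent archetype.

    ``completion_time_dist`` is (μ, σ) of a log-normal in seconds.
    ``reattempt_latency_fast``/``_slow`` parameterize the two-component
    re-attempt latency mixture: fast latencies are uniform on the given
    (lo, hi) window (seconds), slow ones log-normal (μ, σ).
    """

    archetype: str
    completion_time_dist: tuple[float, float]
    reattempt_prob: float = 0.0
    reattempt_latency_fast: tuple[float, float] = (5.0, 60.0)
    reattempt_latency_slow: tuple[float, float] = (8.0, 1.0)
    fast_latency_weight: float = 0.8
    qualification_gaming_prob: float = 0.0
    trap_compliance_prob: float = 1.0

    def __post_init__(self) -> None:
        for p in (
            self.reattempt_prob,
            self.fast_latency_weight,
            self.qualification_gaming_prob,
            self.trap_compliance_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.completion_time_dist[1] <= 0:
            raise ValueError("log-normal sigma must be positive")


ARCHETYPES: dict[str, ArchetypeParams] = {
    "conscientious": ArchetypeParams(
        "conscientious", (math.log(600.0), 0.4)
    ),
    "speeder_bot": ArchetypeParams(
        "speeder_bot", (math.log(40.0), 0.5), trap_compliance_prob=0.5
    ),
    "fraudulent_repeater": ArchetypeParams(
        "fraudulent_repeater",
        (math.log(90.0), 0.6),
        reattempt_prob=0.85,
        qualification_gaming_prob=0.9,
        trap_compliance_prob=0.8,
    ),
    "inattentive": ArchetypeParams(
        "inattentive", (math.log(300.0), 0.5), trap_compliance_prob=0.85
    ),
}


@dataclass
class CohortConfig:
    """Generative parameters for one synthetic cohort.

    ``replica`` ∈ {None, "study1", "study2"} switches to the pinned
    composition generators, ignoring the mixture.
    """

    n_respondents: int = 200
    archetype_mixture: Mapping[str, float] = field(
        default_factory=lambda: {
            "conscientious": 0.75,
            "speeder_bot": 0.05,
            "fraudulent_repeater": 0.10,
            "inattentive": 0.10,
        }
    )
    condition_prevalence: float = 0.10
    seed: int = 0
    replica: str | None = None

    def __post_init__(self) -> None:
        if self.n_respondents < 0:
            raise ValueError("n_respondents must be non-negative")
        unknown = set(self.archetype_mixture) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetype(s): {sorted(unknown)}")
        total = sum(self.archetype_mixture.values())
        if self.archetype_mixture and abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype mixture sums to {total}, not 1")
        if self.replica not in (None, "study1", "study2"):
            raise ValueError(f"unknown replica {self.replica!r}")


def _answers_for(
    rng: np.random.Generator, sex: str | None, compliance: float
) -> dict[str, str | None]:
    """Trap-item answers: compliant by default, each trap independently
    answered the failing way with probability 1 − compliance."""
    answers: dict[str, str | None] = {}
    fail = lambda: rng.random() > compliance  # noqa: E731
    offset = 0 if not fail() else int(rng.integers(2, 6))
    answers["survey_date"] = f"@{offset}"  # resolved against start date later
    for item in _FICT_ITEMS:
        answers[item] = "yes" if fail() else "no"
    for i, item in enumerate(_SEXTRAP_ITEMS, start=1):
        vulnerable = (sex == "male" and i <= 7) or (sex == "female" and i > 7)
        answers[item] = "yes" if (vulnerable and fail()) else "no"
    has = rng.random() < 0.10
    answers["has_diabetes"] = "yes" if has else "no"
    answers["has_diabetes_confirm"] = (
        "no" if (has and fail()) else ("yes" if has else "no")
    )
    if has:
        both = fail()
        answers["dx_type1"] = "yes"
        answers["dx_type2"] = "yes" if both else "no"
    else:
        answers["dx_type1"] = "no"
        answers["dx_type2"] = "no"
    return answers


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[ResponseRecord], dict]:
    """Draw a cohort from the archetype mixture; returns (table, ledger).

    Deterministic given the seed.  The ledger records each respondent's true
    archetype and attempt count so pipeline statistics can be checked
    against the generator's own bookkeeping.
    """
    if config.replica == "study1":
        return study1_replica(config.seed)
    if config.replica == "study2":
        return study2_replica(config.seed)

    rng = np.random.default_rng(config.seed)
    schema = study2_schema()
    names = sorted(config.archetype_mixture)
    probs = [config.archetype_mixture[n] for n in names]
    records: list[ResponseRecord] = []
    ledger: dict = {"archetype": {}, "n_attempts": {}, "seed": config.seed}
    for i in range(config.n_respondents):
        arch_name = (
            str(rng.choice(names, p=probs)) if names else "conscientious"
        )
        arch = ARCHETYPES[arch_name]
        ip = f"ip{i:06d}"
        ledger["archetype"][ip] = arch_name
        has_condition = rng.random() < config.condition_prevalence
        start = _STUDY2_T0 + int(rng.integers(0, _STUDY2_WINDOW))
        sex = str(rng.choice(["male", "female"]))

        # attempt sequence: fraudulent repeaters re-attempt until they game
        # the qualification page; everyone else answers once
        n_extra = 0
        if arch.reattempt_prob > 0 and not has_condition:
            while n_extra < 5 and rng.random() < arch.reattempt_prob:
                n_extra += 1
        diseases = []
        for a in range(n_extra):
            diseases.append(str(rng.choice(_NON_QUALIFYING)))
        final_games = (
            n_extra > 0 and rng.random() < arch.qualification_gaming_prob
        )
        diseases.append(
            "diabetes"
            if (has_condition or final_games)
            else str(rng.choice(_NON_QUALIFYING))
        )
        ledger["n_attempts"][ip] = len(diseases)

        t = start
        for a, disease in enumerate(diseases):
            final = a == len(diseases) - 1
            duration = float(
                rng.lognormal(*arch.completion_time_dist)
                if final
                else rng.uniform(15, 90)
            )
            answers: dict[str, str | None] = {k: None for k in schema.item_ids}
            if final:
                answers.update(_answers_for(rng, sex, arch.trap_compliance_prob))
                answers["sex"] = sex
                answers["age"] = str(int(rng.integers(18, 70)))
                ref = _dt.datetime.fromtimestamp(t, _dt.timezone.utc).date()
                off = int(answers["survey_date"][1:])
                sign = -1 if rng.random() < 0.5 else 1
                answers["survey_date"] = (ref + _dt.timedelta(days=sign * off)).isoformat()
            records.append(
                ResponseRecord(
                    response_id=f"c{len(records):06d}",
                    ip_key=ip,
                    start_time=t,
                    end_time=t + max(1, int(round(duration))),
                    qualification_disease=disease,
                    qualification_adult=True,
                    answers=answers,
                )
            )
            if not final:
                if rng.random() < arch.fast_latency_weight:
                    gap = rng.uniform(*arch.reattempt_latency_fast)
                else:
                    gap = rng.lognormal(*arch.reattempt_latency_slow)
                t += max(1, int(round(gap)))
    return records, ledger


# ---------------------------------------------------------------------------
# replica of the 4165-response qualification-gated survey


def _expand(rng: np.random.Generator, counts: Sequence[tuple[object, int]]) -> list:
    out: list = []
    for value, n in counts:
        out.extend([value] * n)
    rng.shuffle(out)
    return out


def study1_replica(seed: int = 0) -> tuple[list[ResponseRecord], dict]:
    """Pinned replica of the duplicate-IP-dominated survey log.

    Composition (exact for every seed): 4165 responses total; 2667
    single-attempt non-qualified; 252 single-attempt qualifiers (diabetes
    reported, adult) of whom exactly 49 complete in under 300 s and whose
    later diabetes-type answers split 61/146/11/3 with 31 blank; 1246
    responses from 533 repeat IPs with attempt histogram
    {2: 400, 3: 101, 4: 19, 5: 11, 6: 2}.

    Repeat-IP behavior: 256 groups never report diabetes; 210 flip from a
    non-qualifying answer to diabetes on their final attempt (185 within
    60 s of the preceding attempt, 25 slower); 13 start with diabetes and
    flip away (mean flip latency 12 852 s ≈ 3.57 h); 54 groups leave the
    qualification blank on the first attempt and report diabetes on every
    later one, so they report diabetes without an observable status flip.
    Duplicate diabetes-positive responses total 210 + 13 + 84 = 307, so a
    naive qualification-page-only screen accepts 559 of 4165 (13.42%).
    """
    rng = np.random.default_rng(seed)
    schema = study1_schema()
    records: list[ResponseRecord] = []
    ip_counter = 0
    group_category: dict[str, str] = {}

    def new_ip() -> str:
        nonlocal ip_counter
        ip_counter += 1
        return f"ip{ip_counter:05d}"

    def rand_start() -> int:
        return _STUDY1_T0 + int(rng.integers(0, _STUDY1_WINDOW))

    def add(ip, start, duration, disease, adult=True, answers=None):
        records.append(
            ResponseRecord(
                response_id=f"tmp{len(records)}",
                ip_key=ip,
                start_time=int(start),
                end_time=int(start) + max(0, int(round(duration))),
                qualification_disease=disease,
                qualification_adult=adult,
                answers=answers or {k: None for k in schema.item_ids},
            )
        )

    # --- 2667 single-attempt non-qualified -------------------------------
    for _ in range(2667):
        ip = new_ip()
        group_category[ip] = "single_nonqualified"
        disease = str(rng.choice(_NON_QUALIFYING, p=[0.55, 0.15, 0.20, 0.10]))
        add(ip, rand_start(), rng.uniform(15, 120), disease)

    # --- 252 single-attempt qualifiers -----------------------------------
    dtype_answers = _expand(
        rng,
        [("type1", 61), ("type2", 146), ("dont_know", 11), ("no_diabetes", 3), (None, 31)],
    )
    fast_times = (
        [8.0]
        + list(rng.uniform(20, 60, size=11))  # the near-instant bot-like tail
        + list(rng.uniform(60, 299, size=37))
    )
    slow_times = list(
        np.clip(rng.lognormal(math.log(650.0), 0.85, size=202), 305, 16_000)
    ) + [17_100.0]
    times_252 = fast_times + slow_times  # exactly 49 under the 300-s floor
    rng.shuffle(times_252)
    sexes = _expand(rng, [("male", 95), ("female", 153), (None, 4)])
    races = _expand(
        rng,
        [
            ("non_hispanic_white", 172),
            ("american_indian_alaska_native", 7),
            ("asian_pacific_islander", 19),
            ("hispanic_latino", 16),
            ("black_african_american", 25),
            ("other", 10),
            (None, 3),
        ],
    )
    ages = np.clip(np.round(rng.normal(38.93, 13.6, size=252)), 18, 74)
    for j in range(252):
        ip = new_ip()
        group_category[ip] = "acceptable"
        answers = {
            "diabetes_type": dtype_answers[j],
            "age": str(int(ages[j])),
            "sex": sexes[j],
            "race": races[j],
        }
        add(ip, rand_start(), times_252[j], "diabetes", answers=answers)

    # --- 533 repeat-IP groups --------------------------------------------
    # group sizes by behavioral category; histogram totals {2:400,3:101,4:19,5:11,6:2}
    acquired_sizes = _expand(rng, [(2, 170), (3, 30), (4, 8), (5, 2)])  # 210
    never_sizes = _expand(rng, [(2, 193), (3, 41), (4, 11), (5, 9), (6, 2)])  # 256
    lost_sizes = [2] * 13
    blank_sizes = _expand(rng, [(2, 24), (3, 30)])  # 54

    def dup_answers(disease):
        if disease != "diabetes":
            return None
        return {
            "diabetes_type": str(rng.choice(["type1", "type2", "dont_know"])),
            "age": str(int(rng.integers(18, 70))),
            "sex": str(rng.choice(["male", "female"])),
            "race": "non_hispanic_white",
        }

    fast_flags = [True] * 185 + [False] * 25
    rng.shuffle(fast_flags)
    for size, fast in zip(acquired_sizes, fast_flags):
        ip = new_ip()
        group_category[ip] = "acquired"
        t = rand_start()
        for a in range(size):
            final = a == size - 1
            disease = "diabetes" if final else str(rng.choice(_NON_QUALIFYING))
            add(ip, t, rng.uniform(300, 1200) if final else rng.uniform(15, 90),
                disease, answers=dup_answers(disease))
            if a < size - 1:
                last_gap = a == size - 2
                if last_gap:  # the flip latency
                    gap = rng.uniform(5, 60) if fast else 61 + rng.lognormal(4.5, 1.0)
                else:
                    gap = rng.uniform(5, 120)
                t += max(1, int(round(gap)))

    lost_gaps = rng.normal(12_852.0, 2_500.0, size=13)
    lost_gaps = np.clip(lost_gaps - lost_gaps.mean() + 12_852.0, 3_600, None)
    for size, gap in zip(lost_sizes, lost_gaps):
        ip = new_ip()
        group_category[ip] = "lost"
        t = rand_start()
        add(ip, t, rng.uniform(300, 1200), "diabetes", answers=dup_answers("diabetes"))
        add(ip, t + int(round(gap)), rng.uniform(15, 90), str(rng.choice(_NON_QUALIFYING)))

    for size in blank_sizes:
        ip = new_ip()
        group_category[ip] = "blank_then_diabetes"
        t = rand_start()
        add(ip, t, rng.uniform(10, 60), None)  # qualification left blank
        for _ in range(size - 1):
            t += max(1, int(round(rng.uniform(10, 300))))
            add(ip, t, rng.uniform(300, 1200), "diabetes",
                answers=dup_answers("diabetes"))

    for size in never_sizes:
        ip = new_ip()
        group_category[ip] = "never_diabetes"
        t = rand_start()
        for _ in range(size):
            add(ip, t, rng.uniform(15, 90), str(rng.choice(_NON_QUALIFYING)))
            t += max(1, int(round(rng.uniform(5, 600))))

    # shuffle row order, then assign stable sequential response ids
    rng.shuffle(records)
    for i, rec in enumerate(records):
        rec.response_id = f"r{i + 1:05d}"

    ledger = {
        "seed": seed,
        "total_responses": 4165,
        "single_attempt_nonqualified": 2667,
        "acceptable": 252,
        "acceptable_under_300s": 49,
        "duplicate_responses": 1246,
        "duplicate_ips": 533,
        "attempt_histogram": {2: 400, 3: 101, 4: 19, 5: 11, 6: 2},
        "acquired_events": 210,
        "acquired_fast_60s": 185,
        "lost_events": 13,
        "naive_qualified_responses": 559,
        "group_category": group_category,
        "diabetes_type_counts": {
            "type1": 61, "type2": 146, "dont_know": 11, "no_diabetes": 3, "blank": 31
        },
    }
    return records, ledger


# ---------------------------------------------------------------------------
# replica of the 616-completer two-sample trap-question study


def _demographics(rng: np.random.Generator, sample: str) -> dict[str, list]:
    if sample == "mturk":
        sex = [("male", 138), ("female", 176), (None, 2)]
        # printed race column sums to 315 of 316; the leftover gets a blank
        race = [
            ("non_hispanic_white", 244),
            ("american_indian_alaska_native", 2),
            ("asian_pacific_islander", 24),
            ("hispanic_latino", 12),
            ("black_african_american", 26),
            ("other", 7),
            (None, 1),
        ]
        marital = [
            ("single", 150), ("married_partnered", 115), ("divorced", 42),
            ("separated", 4), ("widowed", 5),
        ]
        education = [
            ("no_high_school", 3), ("high_school", 36), ("some_college", 97),
            ("associates", 39), ("bachelors", 114), ("masters", 22),
            ("professional", 3), ("doctorate", 2),
        ]
    else:
        sex = [("male", 67), ("female", 232), (None, 1)]
        race = [
            ("non_hispanic_white", 222),
            ("american_indian_alaska_native", 3),
            ("asian_pacific_islander", 21),
            ("hispanic_latino", 16),
            ("black_african_american", 17),
            ("other", 18),
            (None, 3),
        ]
        marital = [
            ("single", 291), ("married_partnered", 7), ("divorced", 1), (None, 1),
        ]
        education = [
            ("high_school", 72), ("some_college", 208), ("associates", 11),
            ("bachelors", 7), ("masters", 1), (None, 1),
        ]
    return {
        "sex": _expand(rng, sex),
        "race": _expand(rng, race),
        "marital": _expand(rng, marital),
        "education": _expand(rng, education),
    }


def _ages(rng: np.random.Generator, sample: str, n: int) -> list[int]:
    # right-skewed shifted gammas matched to the printed moments and ranges
    if sample == "mturk":
        lo, hi, k, theta = 20, 69, 2.0, 10.0  # truncated mean ≈ 38.1, SD ≈ 11.1
    else:
        lo, hi, k, theta = 17, 62, 0.637, 3.72  # mean ≈ 19.4, SD ≈ 3.0
    out: list[int] = []
    while len(out) < n:
        draw = lo + rng.gamma(k, theta)
        if draw <= hi:
            out.append(int(round(draw)))
    return out


# planted per-person failure profiles (category lists), per sample; these
# reproduce the printed per-category totals AND the per-person percentage
# distribution simultaneously (verified arithmetically: 41 + 19 = 60 events
# over persons 278/35/3/0 and 285/12/2/1 at counts 0..3)
_MTURK_PROFILES = (
    [("date",)] * 18
    + [("sex",)] * 3
    + [("diab1",)] + [("diab2",)]
    + [("timing",)] * 12
    + [("sex", "sex")] * 2
    + [("date", "timing")]
)
_UG_PROFILES = (
    [("date",)] * 8
    + [("fict",)]
    + [("sex",)]
    + [("timing",)] * 2
    + [("date", "timing")]
    + [("fict", "timing")]
    + [("date", "sex", "timing")]
)
# alert-arm totals for planted failures: 24 under alert, 36 without
_MTURK_ALERT_FAILS = 16
_UG_ALERT_FAILS = 8

# planted completion-time outliers (seconds); fast < 120, slow > 1125,
# spanning the printed range 84 s .. 4740 s
_MTURK_FAST = (84, 95, 100, 108, 112, 118)
_MTURK_SLOW = (1150, 1200, 1220, 1250, 1280, 1300, 1350)
_UG_FAST = (90, 105)
_UG_SLOW = (1230, 1400, 4740)

_POOLED_MEAN = 339.0  # 5 min 39 s
_POOLED_SD = 262.0  # 4 min 22 s


def _unflagged_times(rng: np.random.Generator, n_mturk: int, n_ug: int) -> np.ndarray:
    """Draw in-range completion times and moment-match the pooled sample.

    The crowdsourced arm is systematically faster.  After drawing, an affine
    map is applied to the unflagged block so that the *pooled* cohort
    (flagged outliers included) has mean exactly 339 s and SD exactly 262 s,
    which puts the mean+3·SD ceiling at exactly 1125 s.
    """
    flagged = np.array(_MTURK_FAST + _MTURK_SLOW + _UG_FAST + _UG_SLOW, dtype=float)
    raw_m = 121.0 + rng.lognormal(math.log(120.0), 0.7, size=n_mturk)
    raw_u = 121.0 + rng.lognormal(math.log(230.0), 0.7, size=n_ug)
    raw = np.clip(np.concatenate([raw_m, raw_u]), 130.0, 1000.0)
    n_total = len(raw) + len(flagged)
    target_sum = n_total * _POOLED_MEAN
    target_tss = (n_total - 1) * _POOLED_SD**2
    mean_u_target = (target_sum - flagged.sum()) / len(raw)
    ss_target = target_tss - np.sum((flagged - _POOLED_MEAN) ** 2)
    ss_target -= len(raw) * (mean_u_target - _POOLED_MEAN) ** 2
    ss_own = np.sum((raw - raw.mean()) ** 2)
    b = math.sqrt(ss_target / ss_own)
    a = mean_u_target - b * raw.mean()
    adjusted = a + b * raw
    if adjusted.min() < 120.5 or adjusted.max() > 1125.0:  # pragma: no cover
        raise RuntimeError("moment-matched times left the unflagged window")
    return adjusted


def study2_replica(seed: int = 0) -> tuple[list[ResponseRecord], dict]:
    """Pinned replica of the two-sample trap-question study.

    316 crowdsourced + 300 undergraduate completers; demographics match the
    printed per-sample cell counts exactly; 60 trap failures planted to
    reproduce both the per-category totals (41 / 19 by sample) and the
    per-person failure-count distribution; completion times pooled to mean
    339 s and SD 262 s exactly (so the +3 SD ceiling is 1125 s), spanning
    84 s to 4740 s, with the 18 planted timing outliers split 13 / 5 by
    sample; the alert is assigned to exactly half of each sample, carrying
    24 of the 60 planted failures.  ``start_time`` is the post-alert clock
    start, so ``completion_seconds`` is the duration the timing rules use.
    """
    rng = np.random.default_rng(seed)
    schema = study2_schema()
    samples = [("mturk", 316), ("undergraduate", 300)]
    profiles = {"mturk": list(_MTURK_PROFILES), "undergraduate": list(_UG_PROFILES)}
    alert_fail_target = {"mturk": _MTURK_ALERT_FAILS, "undergraduate": _UG_ALERT_FAILS}
    fast = {"mturk": list(_MTURK_FAST), "undergraduate": list(_UG_FAST)}
    slow = {"mturk": list(_MTURK_SLOW), "undergraduate": list(_UG_SLOW)}

    unflagged = _unflagged_times(rng, 316 - 13, 300 - 5)
    unflagged_pool = {
        "mturk": list(unflagged[: 316 - 13]),
        "undergraduate": list(unflagged[316 - 13 :]),
    }

    records: list[ResponseRecord] = []
    ledger_people: dict[str, dict] = {}
    planted_by_category: dict[str, dict[str, int]] = {}
    rid = 0
    for sample, n in samples:
        demo = _demographics(rng, sample)
        ages = _ages(rng, sample, n)
        blank_age = set(rng.choice(n, size=8, replace=False))  # 16 missing ages total
        # persons with a specified sex are eligible to carry sex-trap failures
        sexed = [i for i in range(n) if demo["sex"][i] is not None]
        rng.shuffle(sexed)
        prof_list = profiles[sample]
        # assign failure profiles: sex-failing profiles need a sexed person
        assignment: dict[int, tuple[str, ...]] = {}
        sex_profiles = [p for p in prof_list if "sex" in p]
        other_profiles = [p for p in prof_list if "sex" not in p]
        for p in sex_profiles:
            assignment[sexed.pop()] = p
        unassigned = [i for i in range(n) if i not in assignment]
        rng.shuffle(unassigned)
        for p in other_profiles:
            assignment[unassigned.pop()] = p

        # alert arms: planted-failure persons are allocated so the alert arm
        # carries the target number of failure events, everyone else fills
        # the half/half split
        n_alert = n // 2
        fail_persons = sorted(assignment, key=lambda i: (-len(assignment[i]), i))
        alert_set: set[int] = set()
        remaining = alert_fail_target[sample]
        for person in fail_persons:
            k = len(assignment[person])
            if k <= remaining:
                alert_set.add(person)
                remaining -= k
            if remaining == 0:
                break
        fillers = [i for i in unassigned if i not in alert_set]
        rng.shuffle(fillers)
        alert_set.update(fillers[: n_alert - len(alert_set)])

        timing_times = fast[sample] + slow[sample]
        rng.shuffle(timing_times)

        vignette_cause = _expand(
            rng, [("lifestyle", n - n // 2), ("genetic", n // 2)]
        )
        vignette_disease = _expand(
            rng, [("diabetes", n - n // 2), ("heart_disease", n // 2)]
        )

        for i in range(n):
            profile = assignment.get(i, ())
            sex = demo["sex"][i]
            start = _STUDY2_T0 + int(rng.integers(0, _STUDY2_WINDOW))
            ref_date = _dt.datetime.fromtimestamp(start, _dt.timezone.utc).date()

            if "timing" in profile:
                duration = float(timing_times.pop())
            else:
                duration = float(unflagged_pool[sample].pop())

            # conscientious defaults
            answers: dict[str, str | None] = {k: None for k in schema.item_ids}
            jitter = int(rng.choice([-1, 0, 1], p=[0.1, 0.8, 0.1]))
            answers["survey_date"] = (ref_date + _dt.timedelta(days=jitter)).isoformat()
            for item in _FICT_ITEMS:
                answers[item] = "no"
            for j, item in enumerate(_SEXTRAP_ITEMS, start=1):
                allowed = (sex == "female" and j <= 7) or (sex == "male" and j > 7)
                answers[item] = "yes" if (allowed and rng.random() < 0.3) else "no"
            has = rng.random() < 0.08
            answers["has_diabetes"] = "yes" if has else "no"
            answers["has_diabetes_confirm"] = "yes" if has else "no"
            answers["dx_type1"] = "yes" if (has and rng.random() < 0.35) else "no"
            answers["dx_type2"] = (
                "yes" if (has and answers["dx_type1"] == "no") else "no"
            )
            answers["sex"] = sex
            answers["race"] = demo["race"][i]
            answers["marital"] = demo["marital"][i]
            answers["education"] = demo["education"][i]
            answers["age"] = None if i in blank_age else str(ages[i])
            answers["vignette_cause"] = vignette_cause[i]
            answers["vignette_disease"] = vignette_disease[i]
            mus = (
                (3.15, 2.01, 2.76)
                if vignette_cause[i] == "lifestyle"
                else (1.44, 1.26, 1.34)
            )
            for item, mu in zip(
                ("rating_responsibility", "rating_anger", "rating_blame"), mus
            ):
                answers[item] = str(int(np.clip(round(rng.normal(mu, 0.85)), 1, 5)))

            # planted failures override the compliant defaults
            n_sex_fails = profile.count("sex")
            if n_sex_fails:
                pool = (
                    list(range(1, 8)) if sex == "male" else list(range(8, 14))
                )
                chosen = rng.choice(pool, size=n_sex_fails, replace=False)
                for j in chosen:
                    answers[f"sextrap_{int(j)}"] = "yes"
            if "date" in profile:
                off = int(rng.integers(2, 6)) * (1 if rng.random() < 0.5 else -1)
                answers["survey_date"] = (
                    ref_date + _dt.timedelta(days=off)
                ).isoformat()
            if "fict" in profile:
                answers[str(rng.choice(_FICT_ITEMS))] = "yes"
            if "diab1" in profile:
                answers["has_diabetes"] = "yes"
                answers["has_diabetes_confirm"] = "no"
                answers["dx_type1"] = "no"
                answers["dx_type2"] = "no"
            if "diab2" in profile:
                answers["has_diabetes"] = "yes"
                answers["has_diabetes_confirm"] = "yes"
                answers["dx_type1"] = "yes"
                answers["dx_type2"] = "yes"

            rid += 1
            response_id = f"s{rid:04d}"
            records.append(
                ResponseRecord(
                    response_id=response_id,
                    ip_key=f"ipq{rid:04d}",
                    start_time=start,
                    end_time=start + int(round(duration)),
                    sample_label=sample,
                    alert_assigned=i in alert_set,
                    answers=answers,
                )
            )
            ledger_people[response_id] = {
                "sample": sample,
                "planted_failures": list(profile),
                "alert": i in alert_set,
            }
        planted_by_category[sample] = {
            "date": sum(p.count("date") for p in prof_list),
            "fictitious": sum(p.count("fict") for p in prof_list),
            "sex": sum(p.count("sex") for p in prof_list),
            "diabetes": sum(p.count("diab1") + p.count("diab2") for p in prof_list),
            "timing": sum(p.count("timing") for p in prof_list),
        }

    rng.shuffle(records)
    ledger = {
        "seed": seed,
        "n_by_sample": {"mturk": 316, "undergraduate": 300},
        "planted_failures_by_category": planted_by_category,
        "total_failures": {"mturk": 41, "undergraduate": 19, "combined": 60},
        "per_person_failure_counts": {
            "mturk": {0: 278, 1: 35, 2: 3, 3: 0},
            "undergraduate": {0: 285, 1: 12, 2: 2, 3: 1},
        },
        "alert_failures": {"alert": 24, "no_alert": 36},
        "pooled_time_mean": _POOLED_MEAN,
        "pooled_time_sd": _POOLED_SD,
        "people": ledger_people,
    }
    return records, ledger
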