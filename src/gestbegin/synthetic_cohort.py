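"""Seedable generator of claims-style pregnancy cohorts with known ground truth.

Real German claims extracts are legally inaccessible, so every other module
is exercised on synthetic cohorts that reproduce the statistical structure
the algorithm assumes: the outcome-class mixture, the share of pregnancies
with no / one / several concordant / several discordant EDD codings, the
birth-date-vs-EDD offset distributions per class (drawn from a
piecewise-linear inverse CDF through published quantile anchors), the
discordance-spread distribution, quarter-stamping of codings within the
four-quarter lookback, and prenatal-exam scheduling relative to the true LMP.

Each generated pregnancy carries a :class:`GroundTruth` row (true LMP, true
EDD, birth offset), so the generator doubles as an exact oracle: with the
discordant share and jitter set to zero, the estimator must recover the true
LMP for every pregnancy with at least one plausible EDD.

:func:`adversarial_cohort` is the deterministic counterpart: hand-built
records pinning every screening-criterion boundary and every resolution
branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .claims_model import (
    BirthClass,
    CalendarQuarter,
    EddCoding,
    ExamEvent,
    ExamKind,
    PregnancyRecord,
)

__all__ = [
    "ANCHOR_PROBS",
    "GeneratorParams",
    "GroundTruth",
    "simulate_cohort",
    "adversarial_cohort",
    "write_ground_truth",
]

# Probability levels of the quantile anchors used for the offset distributions.
ANCHOR_PROBS = (0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95)

# Birth-minus-EDD offset anchors (days) per class at ANCHOR_PROBS, from the
# observed distributions among pregnancies with >=2 concordant EDDs.
DEFAULT_OFFSET_ANCHORS: dict[BirthClass, tuple[int, ...]] = {
    BirthClass.PRETERM: (-78, -61, -42, -31, -25, -22, -20),
    BirthClass.TERM: (-18, -15, -9, -4, 2, 5, 6),
    BirthClass.AFTER_DUE_DATE: (2, 4, 7, 9, 10, 12, 13),
}

# Maximal-difference anchors (days) among discordant EDD sets:
# median 5, interquartile range 3-7, 5-95% range 1-16.
DEFAULT_SPREAD_ANCHORS: tuple[tuple[float, float], ...] = (
    (0.05, 1.0),
    (0.25, 3.0),
    (0.50, 5.0),
    (0.75, 7.0),
    (0.95, 16.0),
)

_ANCHOR_TAIL_EXTENSION_DAYS = 10  # linear tail beyond the q05/q95 anchors


class _PiecewiseLinearQuantile:
    """Inverse-CDF sampler interpolating linearly through (p, value) anchors."""

    def __init__(self, probs, values, tail: float = _ANCHOR_TAIL_EXTENSION_DAYS):
        probs = list(probs)
        values = [float(v) for v in values]
        if any(b <= a for a, b in zip(values, values[1:])):
            raise ValueError(f"quantile anchors must be strictly increasing, got {values}")
        self.probs = np.array([0.0, *probs, 1.0])
        self.values = np.array([values[0] - tail, *values, values[-1] + tail])

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        u = rng.random(n)
        return np.rint(np.interp(u, self.probs, self.values)).astype(np.int64)


@dataclass(frozen=True)
class GeneratorParams:
    """All knobs of the cohort generator; defaults are the emulated study conditions.

    Probability vectors may be given unnormalized (``pattern_mix`` defaults to
    published shares that sum to 1.001 from rounding); they are renormalized
    at draw time but must sum to 1 within 0.01.
    """

    n_pregnancies: int = 10_000
    seed: int = 0
    # preterm / term / after_due_date
    class_mix: tuple[float, float, float] = (0.068, 0.793, 0.139)
    p_no_edd: float = 0.176
    # among pregnancies with >=1 EDD: single / concordant multi / discordant multi
    pattern_mix: tuple[float, float, float] = (0.061, 0.809, 0.131)
    n_codings_range: tuple[int, int] = (2, 4)
    spread_anchors: tuple[tuple[float, float], ...] = DEFAULT_SPREAD_ANCHORS
    offset_anchors: dict[BirthClass, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_OFFSET_ANCHORS)
    )
    p_first_exam_in_window: float = 0.76
    first_exam_window: tuple[int, int] = (28, 56)
    first_exam_spread_range: tuple[int, int] = (0, 140)
    p_antibody_in_window: float = 0.74
    antibody_window: tuple[int, int] = (168, 195)
    antibody_tail_days: int = 28
    first_antibody_ga_range: tuple[int, int] = (63, 112)
    lmp_start: date = date(2006, 1, 1)
    lmp_end: date = date(2015, 12, 31)

    def __post_init__(self) -> None:
        if self.n_pregnancies < 0:
            raise ValueError("n_pregnancies must be >= 0")
        if not 0 <= self.p_no_edd <= 1:
            raise ValueError(f"p_no_edd must be a probability, got {self.p_no_edd}")
        for name in ("class_mix", "pattern_mix"):
            vec = getattr(self, name)
            if any(p < 0 for p in vec):
                raise ValueError(f"{name} has negative entries: {vec}")
            if abs(sum(vec) - 1.0) > 0.01:
                raise ValueError(f"{name} must sum to ~1, got {sum(vec)}")
        for name in ("p_first_exam_in_window", "p_antibody_in_window"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a probability")
        lo, hi = self.n_codings_range
        if not 2 <= lo <= hi:
            raise ValueError(f"n_codings_range must satisfy 2 <= lo <= hi, got {lo, hi}")
        if self.lmp_start >= self.lmp_end:
            raise ValueError("lmp_start must precede lmp_end")
        for cls in BirthClass:
            anchors = self.offset_anchors.get(cls)
            if anchors is None or len(anchors) != len(ANCHOR_PROBS):
                raise ValueError(f"offset_anchors[{cls.value}] must give {len(ANCHOR_PROBS)} values")
            _PiecewiseLinearQuantile(ANCHOR_PROBS, anchors)  # raises if not increasing

    @classmethod
    def from_mapping(cls, config: dict) -> "GeneratorParams":
        """Build params from a config mapping; unknown keys are rejected."""
        known = {f.name for f in fields(cls)}
        unknown = set(config) - known
        if unknown:
            raise ValueError(f"unknown GeneratorParams keys: {sorted(unknown)}")
        coerced = dict(config)
        for key in ("lmp_start", "lmp_end"):
            if key in coerced and isinstance(coerced[key], str):
                coerced[key] = date.fromisoformat(coerced[key])
        if "offset_anchors" in coerced:
            coerced["offset_anchors"] = {
                BirthClass(k): tuple(v) for k, v in coerced["offset_anchors"].items()
            }
        if "spread_anchors" in coerced:
            coerced["spread_anchors"] = tuple(
                (float(p), float(v)) for p, v in coerced["spread_anchors"]
            )
        for key in (
            "class_mix",
            "pattern_mix",
            "n_codings_range",
            "first_exam_window",
            "first_exam_spread_range",
            "antibody_window",
            "first_antibody_ga_range",
        ):
            if key in coerced:
                coerced[key] = tuple(coerced[key])
        return replace(cls(), **coerced)


@dataclass(frozen=True)
class GroundTruth:
    """The latent quantities behind one generated pregnancy."""

    pregnancy_id: str
    true_lmp: date
    true_edd: date
    birth_offset_days: int


_CLASSES = (BirthClass.PRETERM, BirthClass.TERM, BirthClass.AFTER_DUE_DATE)
_PREGNANCY_DAYS = 280


def _normalized(vec) -> np.ndarray:
    arr = np.asarray(vec, dtype=float)
    return arr / arr.sum()


def simulate_cohort(
    params: GeneratorParams,
) -> tuple[list[PregnancyRecord], list[GroundTruth]]:
    """Draw a cohort of live-birth pregnancy records plus their ground truth.

    Per pregnancy: outcome class and true LMP are drawn; the true EDD is
    LMP + 280 days; the birth date is the true EDD plus a class-specific
    offset.  EDD codings follow the no/single/concordant/discordant pattern
    mixture — concordant codings all equal the true EDD, discordant sets keep
    one coding at the true EDD and spread the others to a drawn maximal
    difference, split uniformly between earlier and later.  Each coding is
    stamped into a quarter drawn uniformly from the quarters overlapping the
    pregnancy and not after the birth quarter.  Exam events are placed at
    drawn gestational ages relative to the true LMP; an event whose
    gestational age falls on or after the birth is not emitted (it could not
    have happened).

    Identical ``params`` (including seed) give identical output, row for row.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_pregnancies
    samplers = {
        cls: _PiecewiseLinearQuantile(ANCHOR_PROBS, params.offset_anchors[cls])
        for cls in _CLASSES
    }
    spread_probs = [p for p, _ in params.spread_anchors]
    spread_vals = [v for _, v in params.spread_anchors]
    spread_sampler = _PiecewiseLinearQuantile(
        spread_probs, spread_vals, tail=_ANCHOR_TAIL_EXTENSION_DAYS
    )

    class_idx = rng.choice(3, size=n, p=_normalized(params.class_mix))
    lmp_span = (params.lmp_end - params.lmp_start).days
    lmp_offsets = rng.integers(0, lmp_span + 1, size=n)

    records: list[PregnancyRecord] = []
    truths: list[GroundTruth] = []
    for i in range(n):
        pid = f"P{i:06d}"
        cls = _CLASSES[class_idx[i]]
        lmp = params.lmp_start + timedelta(days=int(lmp_offsets[i]))
        true_edd = lmp + timedelta(days=_PREGNANCY_DAYS)
        offset = int(samplers[cls].sample(rng, 1)[0])
        birth = true_edd + timedelta(days=offset)
        length = (birth - lmp).days
        maternal_age = int(rng.integers(16, 45))

        codings = [
            EddCoding(true_edd + timedelta(days=int(d)), q)
            for d, q in _draw_codings(rng, params, spread_sampler, lmp, birth)
        ]
        exams = _draw_exams(rng, params, lmp, length)

        records.append(
            PregnancyRecord(pid, maternal_age, birth, cls, codings, exams)
        )
        truths.append(GroundTruth(pid, lmp, true_edd, offset))
    return records, truths


def _draw_codings(rng, params: GeneratorParams, spread_sampler, lmp: date, birth: date):
    """Yield (day-offset-from-true-EDD, coding quarter) pairs for one pregnancy."""
    if rng.random() < params.p_no_edd:
        return []
    pattern = int(rng.choice(3, p=_normalized(params.pattern_mix)))
    lo, hi = params.n_codings_range
    if pattern == 0:  # single
        day_offsets = [0]
    elif pattern == 1:  # concordant multi
        day_offsets = [0] * int(rng.integers(lo, hi + 1))
    else:  # discordant multi
        n_cod = int(rng.integers(lo, hi + 1))
        spread = max(1, int(spread_sampler.sample(rng, 1)[0]))
        if n_cod == 2:
            sign = 1 if rng.random() < 0.5 else -1
            day_offsets = [0, sign * spread]
        else:
            early = int(rng.integers(0, spread + 1))
            day_offsets = [0, -early, spread - early]
            day_offsets += [
                int(rng.integers(-early, spread - early + 1)) for _ in range(n_cod - 3)
            ]

    birth_q = CalendarQuarter.of(birth)
    first_q = max(CalendarQuarter.of(lmp).index, birth_q.index - 3)
    quarter_choices = rng.integers(first_q, birth_q.index + 1, size=len(day_offsets))
    return [
        (d, CalendarQuarter.from_index(int(qi)))
        for d, qi in zip(day_offsets, quarter_choices)
    ]


def _draw_exams(rng, params: GeneratorParams, lmp: date, length: int) -> list[ExamEvent]:
    events: list[ExamEvent] = []
    # first prenatal examination
    if rng.random() < params.p_first_exam_in_window:
        lo, hi = params.first_exam_window
    else:
        lo, hi = params.first_exam_spread_range
    ga = int(rng.integers(lo, hi + 1))
    if 0 <= ga < length:
        events.append(ExamEvent(lmp + timedelta(days=ga), ExamKind.FIRST_PRENATAL))

    # antibody screenings: a first test early, the second near weeks 24-27
    flo, fhi = params.first_antibody_ga_range
    first_ga = int(rng.integers(flo, fhi + 1))
    w_lo, w_hi = params.antibody_window
    if rng.random() < params.p_antibody_in_window:
        second_ga = int(rng.integers(w_lo, w_hi + 1))
    else:
        tail = params.antibody_tail_days
        below = rng.random() < 0.5
        second_ga = int(
            rng.integers(w_lo - tail, w_lo) if below else rng.integers(w_hi + 1, w_hi + tail + 1)
        )
    for ga in (first_ga, second_ga):
        if 0 <= ga < length:
            events.append(ExamEvent(lmp + timedelta(days=ga), ExamKind.ANTIBODY_SCREEN))
    return events


def write_ground_truth(truths: list[GroundTruth], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "pregnancy_id": t.pregnancy_id,
            "true_lmp": t.true_lmp.isoformat(),
            "true_edd": t.true_edd.isoformat(),
            "birth_offset_days": t.birth_offset_days,
        }
        for t in truths
    ]
    columns = ["pregnancy_id", "true_lmp", "true_edd", "birth_offset_days"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Deterministic adversarial fixture
# ---------------------------------------------------------------------------


def adversarial_cohort() -> list[PregnancyRecord]:
    """Hand-built records pinning every screening boundary and method branch.

    Covers each exclusion criterion in isolation at its exact threshold
    (survive / exclude one day apart), every EDD-resolution branch including
    the half-day mean-of-modes rounding and a three-way tie, and the
    no-plausible-EDD fallback for all three outcome classes.  Running the
    estimator over the full set yields all seven method labels.
    """
    d = date.fromisoformat
    q = CalendarQuarter
    recs = [
        # criterion i only: EDD one day before its coding quarter opens
        PregnancyRecord(
            "adv-before-quarter", 30, d("2010-07-10"), BirthClass.TERM,
            [EddCoding(d("2010-06-30"), q(2010, 3)),  # excluded (i)
             EddCoding(d("2010-07-01"), q(2010, 3))],  # first day of quarter: survives
        ),
        # criterion ii boundary: 365 days after quarter end survives, 366 excluded
        PregnancyRecord(
            "adv-year-after-quarter", 30, d("2009-12-01"), BirthClass.TERM,
            [EddCoding(d("2010-03-31"), q(2009, 1)),  # last day + 365: survives
             EddCoding(d("2010-04-01"), q(2009, 1))],  # last day + 366: excluded (ii)
        ),
        # criterion iii-a boundary: birth 168 days before EDD survives, 169 excluded
        PregnancyRecord(
            "adv-birth-early", 30, d("2010-01-01"), BirthClass.PRETERM,
            [EddCoding(d("2010-06-18"), q(2009, 4)),  # +168: survives
             EddCoding(d("2010-06-19"), q(2009, 4))],  # +169: excluded (iii-a)
        ),
        # criterion iii-b boundary: birth 21 days after EDD survives, 22 excluded
        PregnancyRecord(
            "adv-birth-late", 30, d("2010-08-23"), BirthClass.AFTER_DUE_DATE,
            [EddCoding(d("2010-08-02"), q(2010, 2)),  # -21: survives
             EddCoding(d("2010-08-01"), q(2010, 2))],  # -22: excluded (iii-b)
        ),
        # criterion iv only: EDD = birth date, coded in vs before the birth quarter
        PregnancyRecord(
            "adv-edd-equals-birth", 30, d("2010-08-05"), BirthClass.TERM,
            [EddCoding(d("2010-08-05"), q(2010, 3)),  # birth quarter: excluded (iv)
             EddCoding(d("2010-08-05"), q(2010, 2))],  # earlier quarter: survives
        ),
        # resolution branches
        PregnancyRecord(
            "adv-single", 30, d("2010-10-04"), BirthClass.TERM,
            [EddCoding(d("2010-10-08"), q(2010, 1))],
        ),
        PregnancyRecord(
            "adv-concordant", 30, d("2010-10-04"), BirthClass.TERM,
            [EddCoding(d("2010-10-08"), q(2010, 1)),
             EddCoding(d("2010-10-08"), q(2010, 2)),
             EddCoding(d("2010-10-08"), q(2010, 2))],
        ),
        PregnancyRecord(
            "adv-mode", 30, d("2010-10-04"), BirthClass.TERM,
            [EddCoding(d("2010-10-08"), q(2010, 2)),
             EddCoding(d("2010-10-08"), q(2010, 3)),
             EddCoding(d("2010-10-13"), q(2010, 3))],
        ),
        # two tied modes five days apart: half-day mean rounds to the earlier day
        PregnancyRecord(
            "adv-mean-halfday", 30, d("2010-10-04"), BirthClass.TERM,
            [EddCoding(d("2010-10-08"), q(2010, 2)),
             EddCoding(d("2010-10-13"), q(2010, 3))],
        ),
        # three-way tie at even spacing: mean is the middle date exactly
        PregnancyRecord(
            "adv-mean-threeway", 30, d("2010-10-04"), BirthClass.TERM,
            [EddCoding(d("2010-10-06"), q(2010, 2)),
             EddCoding(d("2010-10-10"), q(2010, 2)),
             EddCoding(d("2010-10-14"), q(2010, 3))],
        ),
        # fallback paths: no coding at all, or every coding implausible
        PregnancyRecord("adv-fallback-term", 30, d("2010-10-04"), BirthClass.TERM, []),
        PregnancyRecord(
            "adv-fallback-preterm", 30, d("2010-09-07"), BirthClass.PRETERM,
            [EddCoding(d("2010-09-07"), q(2010, 3))],  # excluded (iv) -> fallback
        ),
        PregnancyRecord(
            "adv-fallback-postterm", 30, d("2010-10-17"), BirthClass.AFTER_DUE_DATE, [],
        ),
    ]
    return recs
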