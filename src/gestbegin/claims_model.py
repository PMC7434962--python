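"""Domain types, calendar-quarter arithmetic, and CSV I/O for claims-style pregnancy tables.

German outpatient claims stamp the expected delivery date (EDD) with the
calendar quarter in which it was coded, not an exact coding date.  The types
here model that granularity: a pregnancy carries its birth date, an outcome
class (preterm / term / after due date), a multiset of quarter-stamped EDD
codings, and exactly-dated prenatal examination events.

All dates are ``datetime.date``; all durations are integer day counts.  The
three input tables and the estimates output table are RFC-4180 CSV with
ISO-8601 dates and a mandatory header row.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CalendarQuarter",
    "EddCoding",
    "BirthClass",
    "ExamKind",
    "ExamEvent",
    "PregnancyRecord",
    "AlgorithmConstants",
    "RejectedRow",
    "quarter_bounds",
    "read_cohort",
    "write_cohort",
    "write_estimates",
    "read_estimates",
]

_QUARTER_FIRST_MONTH = {1: 1, 2: 4, 3: 7, 4: 10}


@dataclass(frozen=True, order=True)
class CalendarQuarter:
    """A calendar quarter (year + quarter index 1-4).

    This is the temporal resolution at which EDDs are recorded in the claims:
    the coding event is known only up to its quarter.
    """

    year: int
    quarter: int

    def __post_init__(self) -> None:
        if self.quarter not in (1, 2, 3, 4):
            raise ValueError(f"quarter must be in 1..4, got {self.quarter!r}")

    @property
    def first_day(self) -> date:
        return date(self.year, _QUARTER_FIRST_MONTH[self.quarter], 1)

    @property
    def last_day(self) -> date:
        return self.next().first_day - timedelta(days=1)

    @property
    def index(self) -> int:
        """Linear quarter index; consecutive quarters differ by 1."""
        return self.year * 4 + (self.quarter - 1)

    @classmethod
    def of(cls, d: date) -> "CalendarQuarter":
        return cls(d.year, (d.month - 1) // 3 + 1)

    @classmethod
    def from_index(cls, idx: int) -> "CalendarQuarter":
        return cls(idx // 4, idx % 4 + 1)

    def next(self) -> "CalendarQuarter":
        return CalendarQuarter.from_index(self.index + 1)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.year}Q{self.quarter}"


def quarter_bounds(q: CalendarQuarter) -> tuple[date, date]:
    """First and last calendar day of quarter *q*.

    The span is 90-92 days depending on quarter and leap years.
    """
    return q.first_day, q.last_day


@dataclass(frozen=True)
class EddCoding:
    """One coded expected delivery date plus the quarter in which it was coded."""

    edd: date
    coded_in: CalendarQuarter


class BirthClass(str, enum.Enum):
    """Birth outcome class, assigned upstream from claims codes (an input here)."""

    PRETERM = "preterm"
    TERM = "term"
    AFTER_DUE_DATE = "after_due_date"


class ExamKind(str, enum.Enum):
    FIRST_PRENATAL = "first_prenatal"
    ANTIBODY_SCREEN = "antibody_screen"
    OTHER = "other"


@dataclass(frozen=True)
class ExamEvent:
    date: date
    kind: ExamKind


@dataclass
class PregnancyRecord:
    """One live-birth pregnancy with its EDD codings and exam events.

    ``edd_codings`` preserves input order and multiplicity: an EDD coded twice
    in the same quarter with the same date appears twice, and that multiplicity
    feeds the mode when discordant EDDs are resolved.
    """

    pregnancy_id: str
    maternal_age: int
    birth_date: date
    birth_class: BirthClass
    edd_codings: list[EddCoding] = field(default_factory=list)
    exam_events: list[ExamEvent] = field(default_factory=list)

    @property
    def birth_quarter(self) -> CalendarQuarter:
        return CalendarQuarter.of(self.birth_date)


@dataclass(frozen=True)
class AlgorithmConstants:
    """Every numeric constant of the estimation algorithm, overridable as a unit.

    Day offsets
    -----------
    edd_back_offset_days
        The biologically expected pregnancy duration subtracted from the
        resolved EDD to obtain the beginning of pregnancy (LMP): 280 days.
    fallback_{term,preterm,postterm}_days
        Class-specific median pregnancy lengths used when no plausible EDD
        exists: 276 / 249 / 289 days (German-claims calibration).
    margulis_{term,preterm,postterm}_days
        The published median-length constants (273 / 245 days, with 280 for
        post-term births) used only for the method comparison.

    Plausibility thresholds
    -----------------------
    max_birth_before_edd_days
        Birth more than 24 weeks (168 d) before the EDD is implausible.
    max_birth_after_edd_days
        Birth more than 3 weeks (21 d) after the EDD is implausible.
    max_edd_after_quarter_days
        An EDD more than this many days (365, a fixed-day year so leap years
        cannot flip a verdict) after the last day of its coding quarter is
        implausible.

    Examination windows (gestational days, day 0 = LMP, inclusive)
    ----------------------------------------------------------------
    first_exam_window_days
        Expected window for the first prenatal examination: days 28-56.
    antibody_window_weeks
        Recommended gestational weeks for the second antibody screening:
        24-27, i.e. days 168-195 with week w spanning days [7w, 7w+6].

    Cohort bounds
    -------------
    study_years
        Admissible coding-quarter years (inclusive).
    exam_lookback_days
        Exam events more than this many days before birth (or after birth)
        are rejected at read time.
    """

    edd_back_offset_days: int = 280
    fallback_term_days: int = 276
    fallback_preterm_days: int = 249
    fallback_postterm_days: int = 289
    margulis_term_days: int = 273
    margulis_preterm_days: int = 245
    margulis_postterm_days: int = 280
    max_birth_before_edd_days: int = 168
    max_birth_after_edd_days: int = 21
    max_edd_after_quarter_days: int = 365
    first_exam_window_days: tuple[int, int] = (28, 56)
    antibody_window_weeks: tuple[int, int] = (24, 27)
    study_years: tuple[int, int] = (2004, 2016)
    exam_lookback_days: int = 366

    def __post_init__(self) -> None:
        for name in (
            "edd_back_offset_days",
            "fallback_term_days",
            "fallback_preterm_days",
            "fallback_postterm_days",
            "margulis_term_days",
            "margulis_preterm_days",
            "margulis_postterm_days",
            "max_birth_before_edd_days",
            "max_birth_after_edd_days",
            "max_edd_after_quarter_days",
            "exam_lookback_days",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("first_exam_window_days", "antibody_window_weeks", "study_years"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: lower bound {lo} must be < upper bound {hi}")

    def fallback_days(self, birth_class: BirthClass) -> int:
        return {
            BirthClass.TERM: self.fallback_term_days,
            BirthClass.PRETERM: self.fallback_preterm_days,
            BirthClass.AFTER_DUE_DATE: self.fallback_postterm_days,
        }[BirthClass(birth_class)]

    def margulis_days(self, birth_class: BirthClass) -> int:
        return {
            BirthClass.TERM: self.margulis_term_days,
            BirthClass.PRETERM: self.margulis_preterm_days,
            BirthClass.AFTER_DUE_DATE: self.margulis_postterm_days,
        }[BirthClass(birth_class)]

    @property
    def antibody_window_days(self) -> tuple[int, int]:
        """The recommended antibody-screening weeks as inclusive gestational days."""
        w_lo, w_hi = self.antibody_window_weeks
        return 7 * w_lo, 7 * w_hi + 6

    @classmethod
    def from_mapping(cls, overrides: dict) -> "AlgorithmConstants":
        """Build constants from a config mapping; unknown keys are rejected."""
        known = {f.name for f in fields(cls)}
        unknown = set(overrides) - known
        if unknown:
            raise ValueError(f"unknown AlgorithmConstants keys: {sorted(unknown)}")
        coerced = {
            k: tuple(v) if isinstance(v, (list, tuple)) else v
            for k, v in overrides.items()
        }
        return replace(cls(), **coerced)


@dataclass(frozen=True)
class RejectedRow:
    """One input row rejected during reading, with a human-readable reason."""

    table: str
    pregnancy_id: str
    reason: str


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

PREGNANCY_COLUMNS = ["pregnancy_id", "maternal_age", "birth_date", "birth_class"]
EDD_COLUMNS = ["pregnancy_id", "edd_date", "coded_year", "coded_quarter"]
EXAM_COLUMNS = ["pregnancy_id", "event_date", "event_kind"]
ESTIMATE_COLUMNS = [
    "pregnancy_id",
    "onset_date",
    "method",
    "resolved_edd",
    "n_edds_total",
    "n_edds_plausible",
    "max_discordance_days",
    "exclusion_reasons",
]

MATERNAL_AGE_RANGE = (12, 50)
EDD_LOOKBACK_QUARTERS = 3  # EDDs are searched in the birth quarter and the 3 before


def _read_table(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def _parse_date(text: str) -> date:
    return date.fromisoformat(text.strip())


def read_cohort(
    pregnancy_table: str | Path,
    edd_table: str | Path,
    exam_table: str | Path,
    constants: AlgorithmConstants | None = None,
) -> tuple[list[PregnancyRecord], list[RejectedRow]]:
    """Read and join the three input tables into validated pregnancy records.

    Rows violating a type invariant are rejected with a per-row reason, never
    silently dropped: ``len(records' rows) + len(rejections) == input rows``.
    A rejected pregnancy row drags its child EDD/exam rows into the rejection
    log as orphans.  Structural errors (missing columns) raise ``ValueError``.
    """
    k = constants or AlgorithmConstants()
    preg_df = _read_table(pregnancy_table, PREGNANCY_COLUMNS)
    edd_df = _read_table(edd_table, EDD_COLUMNS)
    exam_df = _read_table(exam_table, EXAM_COLUMNS)

    rejections: list[RejectedRow] = []
    records: dict[str, PregnancyRecord] = {}

    for row in preg_df.itertuples(index=False):
        pid = str(row.pregnancy_id)
        try:
            if pid in records:
                raise ValueError(f"duplicate pregnancy_id {pid!r}")
            age = int(row.maternal_age)
            lo, hi = MATERNAL_AGE_RANGE
            if not lo <= age <= hi:
                raise ValueError(f"maternal_age {age} outside [{lo}, {hi}]")
            birth = _parse_date(row.birth_date)
            birth_class = BirthClass(row.birth_class)
        except ValueError as exc:
            rejections.append(RejectedRow("pregnancies", pid, str(exc)))
            continue
        records[pid] = PregnancyRecord(pid, age, birth, birth_class)

    y_lo, y_hi = k.study_years
    for row in edd_df.itertuples(index=False):
        pid = str(row.pregnancy_id)
        rec = records.get(pid)
        try:
            if rec is None:
                raise ValueError("orphan EDD: no pregnancy row with this id")
            edd = _parse_date(row.edd_date)
            year = int(row.coded_year)
            if not y_lo <= year <= y_hi:
                raise ValueError(f"coded_year {year} outside study window [{y_lo}, {y_hi}]")
            coded_in = CalendarQuarter(year, int(row.coded_quarter))
            lag = rec.birth_quarter.index - coded_in.index
            if not 0 <= lag <= EDD_LOOKBACK_QUARTERS:
                raise ValueError(
                    f"EDD coded in {coded_in}, outside the birth quarter "
                    f"{rec.birth_quarter} and the {EDD_LOOKBACK_QUARTERS} preceding quarters"
                )
        except ValueError as exc:
            rejections.append(RejectedRow("edd_codings", pid, str(exc)))
            continue
        rec.edd_codings.append(EddCoding(edd, coded_in))

    for row in exam_df.itertuples(index=False):
        pid = str(row.pregnancy_id)
        rec = records.get(pid)
        try:
            if rec is None:
                raise ValueError("orphan exam event: no pregnancy row with this id")
            when = _parse_date(row.event_date)
            kind = ExamKind(row.event_kind)
            days_before_birth = (rec.birth_date - when).days
            if days_before_birth > k.exam_lookback_days:
                raise ValueError(
                    f"exam event {when} more than {k.exam_lookback_days} days before birth"
                )
            if days_before_birth < 0:
                raise ValueError(f"exam event {when} after birth date {rec.birth_date}")
        except ValueError as exc:
            rejections.append(RejectedRow("exam_events", pid, str(exc)))
            continue
        rec.exam_events.append(ExamEvent(when, kind))

    return list(records.values()), rejections


def write_cohort(records: Iterable[PregnancyRecord], out_dir: str | Path) -> dict[str, Path]:
    """Write records back out as the three input tables; inverse of :func:`read_cohort`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    preg_rows, edd_rows, exam_rows = [], [], []
    for rec in records:
        preg_rows.append(
            {
                "pregnancy_id": rec.pregnancy_id,
                "maternal_age": rec.maternal_age,
                "birth_date": rec.birth_date.isoformat(),
                "birth_class": rec.birth_class.value,
            }
        )
        for c in rec.edd_codings:
            edd_rows.append(
                {
                    "pregnancy_id": rec.pregnancy_id,
                    "edd_date": c.edd.isoformat(),
                    "coded_year": c.coded_in.year,
                    "coded_quarter": c.coded_in.quarter,
                }
            )
        for e in rec.exam_events:
            exam_rows.append(
                {
                    "pregnancy_id": rec.pregnancy_id,
                    "event_date": e.date.isoformat(),
                    "event_kind": e.kind.value,
                }
            )
    paths = {
        "pregnancies": out / "pregnancies.csv",
        "edd_codings": out / "edd_codings.csv",
        "exam_events": out / "exam_events.csv",
    }
    pd.DataFrame(preg_rows, columns=PREGNANCY_COLUMNS).to_csv(paths["pregnancies"], index=False)
    pd.DataFrame(edd_rows, columns=EDD_COLUMNS).to_csv(paths["edd_codings"], index=False)
    pd.DataFrame(exam_rows, columns=EXAM_COLUMNS).to_csv(paths["exam_events"], index=False)
    return paths


def write_estimates(estimates: Iterable, path: str | Path) -> Path:
    """Write onset estimates (with full provenance) to CSV; empty input yields a header-only file."""
    rows = []
    for est in estimates:
        rows.append(
            {
                "pregnancy_id": est.pregnancy_id,
                "onset_date": est.onset.isoformat(),
                "method": est.method.value,
                "resolved_edd": est.resolved_edd.isoformat() if est.resolved_edd else "",
                "n_edds_total": est.n_edds_total,
                "n_edds_plausible": est.n_edds_plausible,
                "max_discordance_days": est.max_discordance_days,
                "exclusion_reasons": ";".join(est.exclusion_reasons),
            }
        )
    path = Path(path)
    pd.DataFrame(rows, columns=ESTIMATE_COLUMNS).to_csv(path, index=False)
    return path


def read_estimates(path: str | Path) -> list:
    """Read an estimates CSV back into :class:`~gestbegin.onset_estimator.OnsetEstimate` objects."""
    from .onset_estimator import EstimationMethod, OnsetEstimate

    df = _read_table(path, ESTIMATE_COLUMNS)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            OnsetEstimate(
                pregnancy_id=str(row.pregnancy_id),
                onset=_parse_date(row.onset_date),
                method=EstimationMethod(row.method),
                resolved_edd=_parse_date(row.resolved_edd) if row.resolved_edd else None,
                n_edds_total=int(row.n_edds_total),
                n_edds_plausible=int(row.n_edds_plausible),
                max_discordance_days=int(row.max_discordance_days),
                exclusion_reasons=tuple(r for r in row.exclusion_reasons.split(";") if r),
            )
        )
    return out
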