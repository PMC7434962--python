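"""Plausibility screening of coded expected delivery dates.

Four criteria mark an EDD coding as obviously implausible:

i.   the EDD precedes the first day of the quarter in which it was coded
     (a due date cannot predate its own coding window);
ii.  the EDD lies more than one year (365 days) after the last day of the
     coding quarter (too far in the future to be a genuine due date);
iii. the actual birth happened more than 24 weeks (168 days) before the EDD,
     or more than 3 weeks (21 days) after it;
iv.  the EDD was coded in the quarter of the birth and equals the birth date
     exactly — such an entry may simply record the already-known birth date
     (e.g. a scheduled C-section) rather than a prospective due date.

All thresholds are strict ("earlier than" / "more than"): an EDD exactly 168
days after the birth, exactly 21 days before it, exactly on the quarter's
first day, or exactly 365 days after the quarter survives.  Criteria are
evaluated independently, never short-circuited, so an excluded coding carries
every applicable reason.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable

import pandas as pd

from .claims_model import (
    AlgorithmConstants,
    CalendarQuarter,
    EddCoding,
    PregnancyRecord,
)

__all__ = [
    "ExclusionReason",
    "ScreenedCoding",
    "check_edd",
    "screen_pregnancy",
    "screen_cohort",
    "write_exclusions",
]


class ExclusionReason(str, enum.Enum):
    BEFORE_CODING_QUARTER = "before_coding_quarter"
    OVER_ONE_YEAR_AFTER_QUARTER = "over_one_year_after_quarter"
    BIRTH_TOO_EARLY_VS_EDD = "birth_too_early_vs_edd"
    BIRTH_TOO_LATE_VS_EDD = "birth_too_late_vs_edd"
    EQUALS_BIRTH_IN_BIRTH_QUARTER = "equals_birth_in_birth_quarter"


@dataclass(frozen=True)
class ScreenedCoding:
    """An excluded coding together with every reason that applies."""

    coding: EddCoding
    reasons: tuple[ExclusionReason, ...]


def check_edd(
    coding: EddCoding,
    birth_date: date,
    birth_quarter: CalendarQuarter,
    k: AlgorithmConstants | None = None,
) -> tuple[bool, list[ExclusionReason]]:
    """Evaluate all four plausibility criteria for one EDD coding.

    Returns ``(plausible, reasons)`` where *plausible* is true iff *reasons*
    is empty.  Total on valid inputs; never raises.
    """
    k = k or AlgorithmConstants()
    reasons: list[ExclusionReason] = []
    q_first, q_last = coding.coded_in.first_day, coding.coded_in.last_day

    if coding.edd < q_first:
        reasons.append(ExclusionReason.BEFORE_CODING_QUARTER)
    if coding.edd > q_last + timedelta(days=k.max_edd_after_quarter_days):
        reasons.append(ExclusionReason.OVER_ONE_YEAR_AFTER_QUARTER)
    if (coding.edd - birth_date).days > k.max_birth_before_edd_days:
        reasons.append(ExclusionReason.BIRTH_TOO_EARLY_VS_EDD)
    if (birth_date - coding.edd).days > k.max_birth_after_edd_days:
        reasons.append(ExclusionReason.BIRTH_TOO_LATE_VS_EDD)
    # Criterion iv applies only when the coding sits in the birth quarter: an
    # EDD equal to the birth date but coded earlier is a genuinely prophetic
    # due date, not a transcribed birth date.
    if coding.coded_in == birth_quarter and coding.edd == birth_date:
        reasons.append(ExclusionReason.EQUALS_BIRTH_IN_BIRTH_QUARTER)

    return not reasons, reasons


def screen_pregnancy(
    rec: PregnancyRecord, k: AlgorithmConstants | None = None
) -> tuple[list[EddCoding], list[ScreenedCoding]]:
    """Partition a pregnancy's EDD codings into survivors and an exclusion log.

    Survivors preserve input order and multiplicity;
    ``len(survivors) + len(log) == len(rec.edd_codings)``.
    """
    k = k or AlgorithmConstants()
    survivors: list[EddCoding] = []
    log: list[ScreenedCoding] = []
    bq = rec.birth_quarter
    for coding in rec.edd_codings:
        plausible, reasons = check_edd(coding, rec.birth_date, bq, k)
        if plausible:
            survivors.append(coding)
        else:
            log.append(ScreenedCoding(coding, tuple(reasons)))
    return survivors, log


def screen_cohort(
    records: Iterable[PregnancyRecord], k: AlgorithmConstants | None = None
) -> dict[str, tuple[list[EddCoding], list[ScreenedCoding]]]:
    """Screen every pregnancy; keyed by pregnancy_id."""
    k = k or AlgorithmConstants()
    return {rec.pregnancy_id: screen_pregnancy(rec, k) for rec in records}


def write_exclusions(
    screened: dict[str, tuple[list[EddCoding], list[ScreenedCoding]]],
    path: str | Path,
) -> Path:
    """Write the cohort-wide exclusion log (one row per excluded coding)."""
    rows = []
    for pid, (_, log) in screened.items():
        for item in log:
            rows.append(
                {
                    "pregnancy_id": pid,
                    "edd_date": item.coding.edd.isoformat(),
                    "coded_year": item.coding.coded_in.year,
                    "coded_quarter": item.coding.coded_in.quarter,
                    "reasons": ";".join(r.value for r in item.reasons),
                }
            )
    path = Path(path)
    columns = ["pregnancy_id", "edd_date", "coded_year", "coded_quarter", "reasons"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
    return path
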