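"""Estimate the beginning of pregnancy (LMP) for each record.

The estimator proceeds in three steps:

1. screen the pregnancy's EDD codings for plausibility (:mod:`.edd_screen`);
2. if at least one plausible EDD remains, resolve the multiset to a single
   working EDD — the date itself if there is one coding or all are concordant,
   otherwise the mode (most frequently coded date), or the mean of the tied
   modes when the maximal frequency is shared — and subtract 280 days, the
   biologically expected duration of pregnancy;
3. with no plausible EDD, fall back to subtracting a class-specific median
   pregnancy length from the birth date: 276 days for term births, 249 for
   preterm births, 289 for births after the due date.

The published median-length method (273 / 245 days, 280 for post-term) is
also provided, solely so the validation suite can compare the two approaches.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Sequence

from .claims_model import (
    AlgorithmConstants,
    BirthClass,
    EddCoding,
    PregnancyRecord,
)
from .edd_screen import screen_pregnancy

__all__ = [
    "EstimationMethod",
    "ResolveBranch",
    "OnsetEstimate",
    "max_pairwise_difference",
    "resolve_edd",
    "estimate_onset_edd",
    "estimate_onset_fallback",
    "estimate_onset_margulis",
    "estimate_onset",
    "estimate_cohort",
    "gestational_age_at",
]


class ResolveBranch(str, enum.Enum):
    SINGLE = "single"
    CONCORDANT = "concordant"
    MODE = "mode"
    MEAN_OF_MODES = "mean_of_modes"


class EstimationMethod(str, enum.Enum):
    EDD_SINGLE = "edd_single"
    EDD_CONCORDANT = "edd_concordant"
    EDD_MODE = "edd_mode"
    EDD_MEAN_OF_MODES = "edd_mean_of_modes"
    MEDIAN_LENGTH_TERM = "median_length_term"
    MEDIAN_LENGTH_PRETERM = "median_length_preterm"
    MEDIAN_LENGTH_POSTTERM = "median_length_postterm"


_BRANCH_TO_METHOD = {
    ResolveBranch.SINGLE: EstimationMethod.EDD_SINGLE,
    ResolveBranch.CONCORDANT: EstimationMethod.EDD_CONCORDANT,
    ResolveBranch.MODE: EstimationMethod.EDD_MODE,
    ResolveBranch.MEAN_OF_MODES: EstimationMethod.EDD_MEAN_OF_MODES,
}

_CLASS_TO_FALLBACK_METHOD = {
    BirthClass.TERM: EstimationMethod.MEDIAN_LENGTH_TERM,
    BirthClass.PRETERM: EstimationMethod.MEDIAN_LENGTH_PRETERM,
    BirthClass.AFTER_DUE_DATE: EstimationMethod.MEDIAN_LENGTH_POSTTERM,
}


@dataclass(frozen=True)
class OnsetEstimate:
    """Estimated beginning of pregnancy plus full provenance.

    ``max_discordance_days`` is 0 unless the estimate came from discordant
    EDDs (mode / mean-of-modes branches).  ``exclusion_reasons`` lists the
    distinct screening reasons seen among this pregnancy's excluded codings.
    """

    pregnancy_id: str
    onset: date
    method: EstimationMethod
    resolved_edd: date | None
    n_edds_total: int
    n_edds_plausible: int
    max_discordance_days: int
    exclusion_reasons: tuple[str, ...] = ()


def max_pairwise_difference(edds: Sequence[date]) -> int:
    """Maximum pairwise difference in days; 0 for singleton or all-concordant lists."""
    if not edds:
        raise ValueError("max_pairwise_difference requires a non-empty list")
    return (max(edds) - min(edds)).days


def resolve_edd(plausible: Sequence[EddCoding | date]) -> tuple[date, ResolveBranch]:
    """Collapse a non-empty multiset of plausible EDDs to one working date.

    Singleton -> that date (branch ``single``); all concordant -> that date
    (``concordant``); unique most-frequent date -> the mode (``mode``);
    tied maximal frequency — including all-distinct lists, where every date is
    a mode — -> the arithmetic mean of the tied dates (``mean_of_modes``).
    A fractional (half-day) mean is rounded toward the earlier date, so the
    resolved EDD never drifts later than the tied candidates imply.
    """
    dates = [c.edd if isinstance(c, EddCoding) else c for c in plausible]
    if not dates:
        raise ValueError("resolve_edd requires at least one plausible EDD")
    if len(dates) == 1:
        return dates[0], ResolveBranch.SINGLE
    counts = Counter(dates)
    if len(counts) == 1:
        return dates[0], ResolveBranch.CONCORDANT
    top = max(counts.values())
    modes = sorted(d for d, c in counts.items() if c == top)
    if len(modes) == 1:
        return modes[0], ResolveBranch.MODE
    mean_ordinal = sum(d.toordinal() for d in modes) // len(modes)  # floor = earlier
    return date.fromordinal(mean_ordinal), ResolveBranch.MEAN_OF_MODES


def estimate_onset_edd(resolved_edd: date, k: AlgorithmConstants | None = None) -> date:
    """Back-calculate the LMP from a resolved EDD: EDD minus 280 days."""
    k = k or AlgorithmConstants()
    return resolved_edd - timedelta(days=k.edd_back_offset_days)


def estimate_onset_fallback(
    birth_date: date, birth_class: BirthClass, k: AlgorithmConstants | None = None
) -> date:
    """Median-length fallback: birth date minus 276 / 249 / 289 days by class."""
    k = k or AlgorithmConstants()
    return birth_date - timedelta(days=k.fallback_days(birth_class))


def estimate_onset_margulis(
    birth_date: date, birth_class: BirthClass, k: AlgorithmConstants | None = None
) -> date:
    """Published median-length method: birth date minus 273 / 245 / 280 days by class.

    Used only by the validation suite's method comparison, never by
    :func:`estimate_onset` itself.
    """
    k = k or AlgorithmConstants()
    return birth_date - timedelta(days=k.margulis_days(birth_class))


def estimate_onset(rec: PregnancyRecord, k: AlgorithmConstants | None = None) -> OnsetEstimate:
    """Run the full algorithm on one pregnancy record."""
    k = k or AlgorithmConstants()
    survivors, log = screen_pregnancy(rec, k)
    reasons: list[str] = []
    for item in log:
        for r in item.reasons:
            if r.value not in reasons:
                reasons.append(r.value)

    if survivors:
        resolved, branch = resolve_edd(survivors)
        method = _BRANCH_TO_METHOD[branch]
        discordance = (
            max_pairwise_difference([c.edd for c in survivors])
            if branch in (ResolveBranch.MODE, ResolveBranch.MEAN_OF_MODES)
            else 0
        )
        onset = estimate_onset_edd(resolved, k)
    else:
        method = _CLASS_TO_FALLBACK_METHOD[rec.birth_class]
        resolved = None
        discordance = 0
        onset = estimate_onset_fallback(rec.birth_date, rec.birth_class, k)

    return OnsetEstimate(
        pregnancy_id=rec.pregnancy_id,
        onset=onset,
        method=method,
        resolved_edd=resolved,
        n_edds_total=len(rec.edd_codings),
        n_edds_plausible=len(survivors),
        max_discordance_days=discordance,
        exclusion_reasons=tuple(reasons),
    )


def estimate_cohort(
    records: Iterable[PregnancyRecord], k: AlgorithmConstants | None = None
) -> list[OnsetEstimate]:
    k = k or AlgorithmConstants()
    return [estimate_onset(rec, k) for rec in records]


def gestational_age_at(event_date: date, onset: date) -> tuple[int, int]:
    """Gestational age at *event_date* given the estimated LMP.

    Day 0 is the LMP; completed week ``w`` spans days ``[7w, 7w+6]``.
    Negative day counts (event before the estimated onset) are reported
    as-is so plausibility summaries can count implausibly early events.
    """
    days = (event_date - onset).days
    return days, days // 7
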