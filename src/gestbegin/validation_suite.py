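"""Cohort-level plausibility statistics for the estimated beginning of pregnancy.

The algorithm cannot be validated directly (the true LMP is unobserved in
claims), so plausibility is assessed indirectly:

* availability and concordance of plausible EDD codings;
* the distribution of (birth date − resolved EDD), stratified by outcome
  class and coding pattern — negative values mean the birth preceded the EDD;
* the implied pregnancy-length distribution (birth − estimated onset);
* the gestational age at which the first prenatal examination and the second
  antibody screening were coded, against their clinically expected windows;
* a head-to-head comparison of the EDD method against the published
  median-length method on pregnancies where both are computable.

Quantiles use the inverted-ECDF (type-1) estimator on integer day counts, so
every reported quantile is an observed data point and integer summary tables
are reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .claims_model import (
    AlgorithmConstants,
    BirthClass,
    ExamKind,
    PregnancyRecord,
)
from .onset_estimator import (
    EstimationMethod,
    OnsetEstimate,
    estimate_onset_margulis,
    gestational_age_at,
    max_pairwise_difference,
)

__all__ = [
    "QuantileSummary",
    "AvailabilitySummary",
    "ExamWindowSummary",
    "EDD_PATTERN_STRATA",
    "summarize_availability",
    "summarize_edd_birth_difference",
    "summarize_lengths",
    "summarize_exam_timing",
    "compare_methods",
    "write_validation_report",
]

_EDD_METHODS = {
    EstimationMethod.EDD_SINGLE,
    EstimationMethod.EDD_CONCORDANT,
    EstimationMethod.EDD_MODE,
    EstimationMethod.EDD_MEAN_OF_MODES,
}

# Coding-pattern strata for the EDD-vs-birth difference table.
EDD_PATTERN_STRATA = ("concordant_multi", "only_one", "discordant_multi")

_METHOD_TO_PATTERN = {
    EstimationMethod.EDD_SINGLE: "only_one",
    EstimationMethod.EDD_CONCORDANT: "concordant_multi",
    EstimationMethod.EDD_MODE: "discordant_multi",
    EstimationMethod.EDD_MEAN_OF_MODES: "discordant_multi",
}


@dataclass(frozen=True)
class QuantileSummary:
    """Order statistics of an integer-day sample (inverted-ECDF quantiles)."""

    n: int
    median: int
    q25: int
    q75: int
    q05: int
    q95: int
    q10: int
    q90: int

    @classmethod
    def from_values(cls, values: Sequence[int]) -> "QuantileSummary":
        if len(values) == 0:
            raise ValueError("cannot summarize an empty sample")
        arr = np.asarray(values, dtype=np.int64)
        q = {
            p: int(np.quantile(arr, p, method="inverted_cdf"))
            for p in (0.5, 0.25, 0.75, 0.05, 0.95, 0.10, 0.90)
        }
        return cls(
            n=len(arr),
            median=q[0.5],
            q25=q[0.25],
            q75=q[0.75],
            q05=q[0.05],
            q95=q[0.95],
            q10=q[0.10],
            q90=q[0.90],
        )


@dataclass(frozen=True)
class AvailabilitySummary:
    """Availability and concordance of plausible EDDs over a cohort.

    ``share_any_edd`` is over all pregnancies; the pattern shares are over
    pregnancies with at least one plausible EDD and sum to 1.
    ``discordance_quantiles`` summarizes the maximal pairwise difference among
    pregnancies with discordant EDDs; ``None`` when that stratum is empty.
    """

    n_total: int
    share_any_edd: float
    share_single: float
    share_all_concordant: float
    share_discordant: float
    discordance_quantiles: QuantileSummary | None


@dataclass(frozen=True)
class ExamWindowSummary:
    """Timing of one examination type relative to the estimated onset.

    Shares are over ``n_evaluable`` pregnancies (those with the relevant
    event; for the antibody screening, those with at least two events, the
    second being evaluated).  Fields that apply to only one exam type are
    ``None`` for the other.
    """

    kind: ExamKind
    n_evaluable: int
    window_days: tuple[int, int]
    share_in_window: float
    share_before_window_1wk: float | None = None
    share_after_window_1wk: float | None = None
    share_in_window_pm_1wk: float | None = None
    share_in_window_pm_2wk: float | None = None
    share_before_day20: float | None = None
    share_before_day8: float | None = None


def summarize_availability(
    records: Sequence[PregnancyRecord],
    screened: dict[str, tuple[list, list]],
) -> AvailabilitySummary:
    """Counts of EDD availability / concordance patterns after screening."""
    if not records:
        raise ValueError("cannot summarize an empty cohort")
    n_total = len(records)
    n_any = n_single = n_concordant = n_discordant = 0
    spreads: list[int] = []
    for rec in records:
        survivors, _ = screened[rec.pregnancy_id]
        if not survivors:
            continue
        n_any += 1
        dates = [c.edd for c in survivors]
        if len(dates) == 1:
            n_single += 1
        elif len(set(dates)) == 1:
            n_concordant += 1
        else:
            n_discordant += 1
            spreads.append(max_pairwise_difference(dates))
    return AvailabilitySummary(
        n_total=n_total,
        share_any_edd=n_any / n_total,
        share_single=n_single / n_any if n_any else 0.0,
        share_all_concordant=n_concordant / n_any if n_any else 0.0,
        share_discordant=n_discordant / n_any if n_any else 0.0,
        discordance_quantiles=QuantileSummary.from_values(spreads) if spreads else None,
    )


def _by_id(records: Iterable[PregnancyRecord]) -> dict[str, PregnancyRecord]:
    return {rec.pregnancy_id: rec for rec in records}


def summarize_edd_birth_difference(
    records: Sequence[PregnancyRecord],
    estimates: Sequence[OnsetEstimate],
) -> dict[tuple[str, BirthClass], QuantileSummary]:
    """Quantiles of (birth date − resolved EDD) in days, by coding pattern × class.

    Only pregnancies with at least one plausible EDD contribute; for
    discordant pregnancies the resolved (mode / mean-of-modes) EDD is used.
    Negative values mean the birth occurred before the expected delivery date.
    """
    recs = _by_id(records)
    buckets: dict[tuple[str, BirthClass], list[int]] = {}
    for est in estimates:
        if est.method not in _EDD_METHODS:
            continue
        rec = recs[est.pregnancy_id]
        key = (_METHOD_TO_PATTERN[est.method], rec.birth_class)
        buckets.setdefault(key, []).append((rec.birth_date - est.resolved_edd).days)
    return {key: QuantileSummary.from_values(v) for key, v in buckets.items()}


def summarize_lengths(
    records: Sequence[PregnancyRecord],
    estimates: Sequence[OnsetEstimate],
) -> dict[BirthClass, QuantileSummary]:
    """Pregnancy length (birth − onset) quantiles by class, EDD-method estimates only."""
    recs = _by_id(records)
    buckets: dict[BirthClass, list[int]] = {}
    for est in estimates:
        if est.method not in _EDD_METHODS:
            continue
        rec = recs[est.pregnancy_id]
        buckets.setdefault(rec.birth_class, []).append((rec.birth_date - est.onset).days)
    return {cls: QuantileSummary.from_values(v) for cls, v in buckets.items()}


def _exam_gestational_day(
    rec: PregnancyRecord, est: OnsetEstimate, kind: ExamKind
) -> int | None:
    """Gestational day of the evaluated event of *kind*, or None if not evaluable.

    First prenatal examination: the earliest such event.  Antibody screening:
    the chronologically second event, and only for pregnancies with at least
    two antibody events (a lone event cannot be the *second* screening).
    """
    dates = sorted(e.date for e in rec.exam_events if e.kind == kind)
    if kind == ExamKind.FIRST_PRENATAL:
        if not dates:
            return None
        evaluated = dates[0]
    elif kind == ExamKind.ANTIBODY_SCREEN:
        if len(dates) < 2:
            return None
        evaluated = dates[1]
    else:
        raise ValueError(f"no timing window defined for exam kind {kind!r}")
    days, _ = gestational_age_at(evaluated, est.onset)
    return days


def summarize_exam_timing(
    records: Sequence[PregnancyRecord],
    estimates: Sequence[OnsetEstimate],
    kind: ExamKind,
    k: AlgorithmConstants | None = None,
    window: tuple[int, int] | None = None,
) -> ExamWindowSummary:
    """Share of pregnancies whose examination falls in its expected window.

    Windows are inclusive gestational-day intervals: days 28–56 for the first
    prenatal examination; days 168–195 (weeks 24–27) for the second antibody
    screening, with the one-week-before/-after margins and the ±1- and
    ±2-week widenings also reported.
    """
    k = k or AlgorithmConstants()
    if window is None:
        window = (
            k.first_exam_window_days
            if kind == ExamKind.FIRST_PRENATAL
            else k.antibody_window_days
        )
    lo, hi = window
    est_by_id = {e.pregnancy_id: e for e in estimates}
    ga_days = []
    for rec in records:
        est = est_by_id.get(rec.pregnancy_id)
        if est is None:
            continue
        day = _exam_gestational_day(rec, est, kind)
        if day is not None:
            ga_days.append(day)
    n = len(ga_days)

    def share(pred) -> float:
        return sum(1 for d in ga_days if pred(d)) / n if n else 0.0

    common = dict(
        kind=kind,
        n_evaluable=n,
        window_days=window,
        share_in_window=share(lambda d: lo <= d <= hi),
    )
    if kind == ExamKind.FIRST_PRENATAL:
        return ExamWindowSummary(
            **common,
            share_before_day20=share(lambda d: d < 20),
            share_before_day8=share(lambda d: d < 8),
        )
    return ExamWindowSummary(
        **common,
        share_before_window_1wk=share(lambda d: lo - 7 <= d < lo),
        share_after_window_1wk=share(lambda d: hi < d <= hi + 7),
        share_in_window_pm_1wk=share(lambda d: lo - 7 <= d <= hi + 7),
        share_in_window_pm_2wk=share(lambda d: lo - 14 <= d <= hi + 14),
    )


def compare_methods(
    records: Sequence[PregnancyRecord],
    estimates: Sequence[OnsetEstimate],
    k: AlgorithmConstants | None = None,
) -> dict[BirthClass, QuantileSummary]:
    """Per-class quantiles of (EDD-method onset − median-length onset) in days.

    Computed over pregnancies with at least one plausible EDD, where both
    methods are defined.  Negative values mean the EDD method places the
    beginning of pregnancy earlier than the published median-length method.
    """
    k = k or AlgorithmConstants()
    recs = _by_id(records)
    buckets: dict[BirthClass, list[int]] = {}
    for est in estimates:
        if est.method not in _EDD_METHODS:
            continue
        rec = recs[est.pregnancy_id]
        margulis = estimate_onset_margulis(rec.birth_date, rec.birth_class, k)
        buckets.setdefault(rec.birth_class, []).append((est.onset - margulis).days)
    return {cls: QuantileSummary.from_values(v) for cls, v in buckets.items()}


# ---------------------------------------------------------------------------
# Report / histogram output
# ---------------------------------------------------------------------------


def _quantile_rows(stratum: str, qs: QuantileSummary) -> list[dict]:
    rows = []
    for stat in ("median", "q25", "q75", "q05", "q95", "q10", "q90"):
        rows.append(
            {
                "stratum": stratum,
                "statistic": stat,
                "value": getattr(qs, stat),
                "denominator": qs.n,
            }
        )
    return rows


def _histogram_frame(values: Sequence[int], label: str) -> pd.DataFrame:
    """Day-resolution counts, the tabular equivalent of the timing figures."""
    counts = pd.Series(values, dtype=np.int64).value_counts().sort_index()
    return pd.DataFrame({label: counts.index, "count": counts.values})


def write_validation_report(
    records: Sequence[PregnancyRecord],
    estimates: Sequence[OnsetEstimate],
    screened: dict[str, tuple[list, list]],
    out_dir: str | Path,
    k: AlgorithmConstants | None = None,
) -> dict[str, Path]:
    """Compute every validation statistic and write the report + histogram CSVs.

    ``validation_report.csv`` has one row per statistic (stratum, statistic,
    value, denominator); histogram CSVs give day-resolution counts for the
    exam-timing and difference distributions.
    """
    k = k or AlgorithmConstants()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []

    avail = summarize_availability(records, screened)
    for name in ("share_any_edd", "share_single", "share_all_concordant", "share_discordant"):
        denom = avail.n_total if name == "share_any_edd" else round(avail.n_total * avail.share_any_edd)
        rows.append(
            {"stratum": "availability", "statistic": name, "value": getattr(avail, name), "denominator": denom}
        )
    if avail.discordance_quantiles is not None:
        rows.extend(_quantile_rows("discordance_days", avail.discordance_quantiles))

    for (pattern, cls), qs in summarize_edd_birth_difference(records, estimates).items():
        rows.extend(_quantile_rows(f"edd_birth_diff/{pattern}/{cls.value}", qs))
    for cls, qs in summarize_lengths(records, estimates).items():
        rows.extend(_quantile_rows(f"pregnancy_length/{cls.value}", qs))
    for cls, qs in compare_methods(records, estimates, k).items():
        rows.extend(_quantile_rows(f"method_difference/{cls.value}", qs))

    for kind in (ExamKind.FIRST_PRENATAL, ExamKind.ANTIBODY_SCREEN):
        summ = summarize_exam_timing(records, estimates, kind, k)
        for f in (
            "share_in_window",
            "share_before_window_1wk",
            "share_after_window_1wk",
            "share_in_window_pm_1wk",
            "share_in_window_pm_2wk",
            "share_before_day20",
            "share_before_day8",
        ):
            val = getattr(summ, f)
            if val is not None:
                rows.append(
                    {
                        "stratum": f"exam_timing/{kind.value}",
                        "statistic": f,
                        "value": val,
                        "denominator": summ.n_evaluable,
                    }
                )

    paths: dict[str, Path] = {}
    report = out / "validation_report.csv"
    pd.DataFrame(rows, columns=["stratum", "statistic", "value", "denominator"]).to_csv(
        report, index=False
    )
    paths["report"] = report

    # Histogram CSVs (the figures, at day resolution).
    est_by_id = {e.pregnancy_id: e for e in estimates}
    for kind, stem in (
        (ExamKind.FIRST_PRENATAL, "hist_first_prenatal_ga"),
        (ExamKind.ANTIBODY_SCREEN, "hist_antibody_second_ga"),
    ):
        days = [
            d
            for rec in records
            if (e := est_by_id.get(rec.pregnancy_id)) is not None
            and (d := _exam_gestational_day(rec, e, kind)) is not None
        ]
        p = out / f"{stem}.csv"
        _histogram_frame(days, "gestational_day").to_csv(p, index=False)
        paths[stem] = p

    recs = _by_id(records)
    diffs = [
        (recs[e.pregnancy_id].birth_date - e.resolved_edd).days
        for e in estimates
        if e.method in _EDD_METHODS
    ]
    p = out / "hist_birth_minus_edd.csv"
    _histogram_frame(diffs, "birth_minus_edd_days").to_csv(p, index=False)
    paths["hist_birth_minus_edd"] = p
    return paths
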