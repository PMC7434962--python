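"""Cohort statistics: quantile oracle, availability counting, analytic identities."""

import math
from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gestbegin.claims_model import (
    BirthClass,
    CalendarQuarter,
    EddCoding,
    ExamEvent,
    ExamKind,
    PregnancyRecord,
)
from gestbegin.edd_screen import screen_cohort
from gestbegin.onset_estimator import estimate_cohort, estimate_onset_margulis
from gestbegin.validation_suite import (
    QuantileSummary,
    compare_methods,
    summarize_availability,
    summarize_edd_birth_difference,
    summarize_exam_timing,
    summarize_lengths,
    write_validation_report,
)
from tests.conftest import make_concordant_record

D = date.fromisoformat


def _sort_oracle(values, p):
    """Type-1 (inverted ECDF) quantile: the ceil(p*n)-th order statistic."""
    s = sorted(values)
    idx = max(math.ceil(p * len(s)), 1) - 1
    return s[idx]


@given(st.lists(st.integers(-120, 120), min_size=1, max_size=60))
@settings(max_examples=300, deadline=None)
def test_quantiles_match_sort_oracle(values):
    qs = QuantileSummary.from_values(values)
    assert qs.n == len(values)
    for attr, p in [
        ("q05", 0.05), ("q10", 0.10), ("q25", 0.25), ("median", 0.5),
        ("q75", 0.75), ("q90", 0.90), ("q95", 0.95),
    ]:
        assert getattr(qs, attr) == _sort_oracle(values, p)
    assert qs.q05 <= qs.q10 <= qs.q25 <= qs.median <= qs.q75 <= qs.q90 <= qs.q95


def test_quantiles_reject_empty():
    with pytest.raises(ValueError):
        QuantileSummary.from_values([])


def _fixture_cohort(diffs_by_class):
    """Concordant-EDD pregnancies whose (birth - EDD) differences are prescribed."""
    records = []
    edd = D("2010-10-08")
    i = 0
    for cls, diffs in diffs_by_class.items():
        for diff in diffs:
            records.append(
                make_concordant_record(f"F{i}", edd + timedelta(days=diff), cls, edd)
            )
            i += 1
    return records


TABLE1_QUARTILE_DIFFS = {
    BirthClass.TERM: [-9, -4, 2],
    BirthClass.PRETERM: [-42, -31, -25],
    BirthClass.AFTER_DUE_DATE: [7, 9, 10],
}


def test_edd_birth_difference_quartile_fixture():
    """Three term pregnancies at the published quartile offsets reproduce them."""
    records = _fixture_cohort({BirthClass.TERM: [-9, -4, 2]})
    qs = summarize_edd_birth_difference(records, estimate_cohort(records))
    summary = qs[("concordant_multi", BirthClass.TERM)]
    assert (summary.median, summary.q25, summary.q75) == (-4, -9, 2)


def test_single_pregnancy_quantiles_degenerate():
    records = _fixture_cohort({BirthClass.TERM: [-4]})
    # a single coding resolves via the single-EDD branch
    records[0].edd_codings = records[0].edd_codings[:1]
    qs = summarize_edd_birth_difference(records, estimate_cohort(records))
    summary = qs[("only_one", BirthClass.TERM)]
    assert summary.n == 1
    assert {summary.median, summary.q05, summary.q95} == {-4}


@pytest.mark.parametrize(
    "cls,diffs,lengths,median_length",
    [
        (BirthClass.TERM, [-9, -4, 2], [271, 276, 282], 276),
        (BirthClass.PRETERM, [-42, -31, -25], [238, 249, 255], 249),
        (BirthClass.AFTER_DUE_DATE, [7, 9, 10], [287, 289, 290], 289),
    ],
)
def test_length_medians_from_quartile_fixtures(cls, diffs, lengths, median_length):
    """length = 280 + (birth - EDD): quartile fixtures give the published medians."""
    records = _fixture_cohort({cls: diffs})
    summary = summarize_lengths(records, estimate_cohort(records))[cls]
    assert summary.median == median_length
    assert sorted([summary.q25, summary.median, summary.q75]) == lengths


@pytest.mark.parametrize(
    "cls,diffs,median_diff",
    [
        (BirthClass.TERM, [-9, -4, 2], -3),
        (BirthClass.PRETERM, [-42, -31, -25], -4),
    ],
)
def test_method_comparison_medians(cls, diffs, median_diff):
    """EDD-method onset minus median-length onset: (EDD-birth) - 7 (term) or - 35 (preterm)."""
    records = _fixture_cohort({cls: diffs})
    summary = compare_methods(records, estimate_cohort(records))[cls]
    assert summary.median == median_diff


def test_method_comparison_single_record_identity():
    # birth = EDD - 4: EDD-method onset = EDD - 280, median-length onset = birth - 273,
    # so the difference is (EDD - birth) - 7 = 4 - 7 = -3 days.
    records = _fixture_cohort({BirthClass.TERM: [-4]})
    summary = compare_methods(records, estimate_cohort(records))[BirthClass.TERM]
    assert summary.median == -3


def test_method_difference_identity_per_pregnancy(small_cohort):
    """diff = (EDD - birth) + (margulis_length - 280), exactly, per pregnancy."""
    records, _ = small_cohort
    ests = {e.pregnancy_id: e for e in estimate_cohort(records)}
    shift = {BirthClass.TERM: -7, BirthClass.PRETERM: -35, BirthClass.AFTER_DUE_DATE: 0}
    for rec in records:
        est = ests[rec.pregnancy_id]
        if est.resolved_edd is None:
            continue
        margulis = estimate_onset_margulis(rec.birth_date, rec.birth_class)
        assert (est.onset - margulis).days == (
            (est.resolved_edd - rec.birth_date).days + shift[rec.birth_class]
        )


def test_median_length_identity_links_tables(large_cohort):
    """median(length) = 280 + median(birth - resolved EDD) per class stratum."""
    records, _ = large_cohort
    ests = estimate_cohort(records)
    lengths = summarize_lengths(records, ests)
    recs = {r.pregnancy_id: r for r in records}
    diffs_by_class = {}
    for e in ests:
        if e.resolved_edd is None:
            continue
        r = recs[e.pregnancy_id]
        diffs_by_class.setdefault(r.birth_class, []).append((r.birth_date - e.resolved_edd).days)
    for cls, diffs in diffs_by_class.items():
        assert lengths[cls].median == 280 + int(np.quantile(diffs, 0.5, method="inverted_cdf"))


def test_availability_counting():
    """4 pregnancies: none / single / 2 concordant / 2 discordant."""
    edd = D("2010-10-08")
    q = CalendarQuarter(2010, 2)
    records = [
        PregnancyRecord("A", 30, D("2010-10-04"), BirthClass.TERM, []),
        PregnancyRecord("B", 30, D("2010-10-04"), BirthClass.TERM, [EddCoding(edd, q)]),
        PregnancyRecord("C", 30, D("2010-10-04"), BirthClass.TERM, [EddCoding(edd, q)] * 2),
        PregnancyRecord(
            "D", 30, D("2010-10-04"), BirthClass.TERM,
            [EddCoding(edd, q), EddCoding(edd + timedelta(days=6), q)],
        ),
    ]
    avail = summarize_availability(records, screen_cohort(records))
    assert avail.n_total == 4
    assert avail.share_any_edd == 0.75
    assert avail.share_single == avail.share_all_concordant == avail.share_discordant == pytest.approx(1 / 3)
    assert avail.discordance_quantiles.n == 1 and avail.discordance_quantiles.median == 6
    assert (
        avail.share_single + avail.share_all_concordant + avail.share_discordant
        == pytest.approx(1.0)
    )


def test_availability_all_concordant_degenerate():
    records = [
        make_concordant_record("A", D("2010-10-04"), BirthClass.TERM, D("2010-10-08")),
        make_concordant_record("B", D("2010-10-05"), BirthClass.TERM, D("2010-10-08")),
    ]
    avail = summarize_availability(records, screen_cohort(records))
    assert avail.share_discordant == 0.0
    assert avail.discordance_quantiles is None


def test_availability_rejects_empty_cohort():
    with pytest.raises(ValueError):
        summarize_availability([], {})


def _with_exams(rec, exam_dates_kinds):
    rec.exam_events = [ExamEvent(D(d), k) for d, k in exam_dates_kinds]
    return rec


def test_first_exam_window():
    rec = make_concordant_record("P1", D("2010-10-04"), BirthClass.TERM, D("2010-10-08"))
    # onset resolves to 2010-01-01; day 40 falls inside days 28-56
    _with_exams(rec, [("2010-02-10", ExamKind.FIRST_PRENATAL)])
    summ = summarize_exam_timing([rec], estimate_cohort([rec]), ExamKind.FIRST_PRENATAL)
    assert summ.n_evaluable == 1 and summ.share_in_window == 1.0
    assert summ.share_before_day20 == 0.0 and summ.share_before_day8 == 0.0


def test_antibody_second_event_evaluated():
    rec = make_concordant_record("P1", D("2010-10-04"), BirthClass.TERM, D("2010-10-08"))
    # onset 2010-01-01; events at gestational days 100 and 170; day 170 is in weeks 24-27
    _with_exams(
        rec,
        [("2010-04-11", ExamKind.ANTIBODY_SCREEN), ("2010-06-20", ExamKind.ANTIBODY_SCREEN)],
    )
    summ = summarize_exam_timing([rec], estimate_cohort([rec]), ExamKind.ANTIBODY_SCREEN)
    assert summ.n_evaluable == 1 and summ.share_in_window == 1.0
    assert summ.share_in_window_pm_1wk == 1.0


def test_single_antibody_event_excluded_from_denominator():
    rec = make_concordant_record("P1", D("2010-10-04"), BirthClass.TERM, D("2010-10-08"))
    _with_exams(rec, [("2010-06-20", ExamKind.ANTIBODY_SCREEN)])
    summ = summarize_exam_timing([rec], estimate_cohort([rec]), ExamKind.ANTIBODY_SCREEN)
    assert summ.n_evaluable == 0


def test_validation_report_schema(tmp_path, small_cohort):
    """Every statistic appears with an explicit denominator."""
    import pandas as pd

    records, _ = small_cohort
    ests = estimate_cohort(records)
    screened = screen_cohort(records)
    paths = write_validation_report(records, ests, screened, tmp_path)
    df = pd.read_csv(paths["report"])
    assert list(df.columns) == ["stratum", "statistic", "value", "denominator"]
    assert df["denominator"].notna().all()
    strata = set(df["stratum"])
    assert "availability" in strata
    assert any(s.startswith("pregnancy_length/") for s in strata)
    assert any(s.startswith("edd_birth_diff/") for s in strata)
    assert any(s.startswith("method_difference/") for s in strata)
    assert any(s.startswith("exam_timing/") for s in strata)
    for stem in ("hist_first_prenatal_ga", "hist_antibody_second_ga", "hist_birth_minus_edd"):
        assert paths[stem].exists()
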