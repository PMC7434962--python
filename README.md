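# gestbegin

Rule-based estimation of the **beginning of pregnancy** (the last menstrual
period, LMP) in claims-style administrative health data, for
pharmacoepidemiologists studying drug safety in pregnancy. Knowing the LMP is
what turns a dispensation date into a gestational age, and hence into an
exposure inside or outside the gestational window vulnerable to a given
teratogen — but the LMP itself is not recorded in claims.

German-style outpatient claims do record the **expected delivery date (EDD)**,
stamped only with the calendar quarter in which it was coded, once or more per
quarter. Since clinicians set EDD = LMP + 280 days (or equivalently from early
ultrasound), the LMP can be recovered by reversing that calculation. The
algorithm implemented here:

1. **Screen** every EDD coding of a pregnancy against four plausibility
   criteria (all strict inequalities): the EDD precedes its coding quarter;
   the EDD lies more than 365 days after the coding quarter's last day; the
   birth is more than 24 weeks (168 d) before or more than 3 weeks (21 d)
   after the EDD; the EDD was coded in the birth quarter and equals the birth
   date (likely a transcribed birth date, not a due date).
2. **Resolve** the surviving multiset to one working EDD: the date itself if
   single or all concordant; otherwise the **mode** (most frequently coded
   date); if several dates tie, the **mean of the modes** (half-days rounded
   to the earlier day).
3. **Back-calculate** the onset: `LMP = EDD_resolved − 280 d`.
4. **Fall back**, when no plausible EDD exists, to class-specific median
   pregnancy lengths: `LMP = birth − 276 d` (term), `− 249 d` (preterm),
   `− 289 d` (birth after due date).

Because real claims extracts are legally access-restricted, the package ships
a seedable **synthetic cohort generator** (with ground-truth LMPs) calibrated
to the published cohort structure, plus an **indirect validation suite**:
EDD availability/concordance, EDD-vs-birth difference quantiles,
pregnancy-length distributions, timing of the first prenatal examination
(expected gestational days 28–56) and of the second antibody screening
(recommended weeks 24–27), and a comparison against the published
median-length method (273 / 245 / 280 d).

## Worked example

Library use on a single record — two concordant EDD codings of 2010-10-08,
term birth on 2010-10-04:

```python
from datetime import date
from gestbegin import (BirthClass, CalendarQuarter, EddCoding,
                       PregnancyRecord, estimate_onset)

rec = PregnancyRecord(
    "P1", 31, date(2010, 10, 4), BirthClass.TERM,
    [EddCoding(date(2010, 10, 8), CalendarQuarter(2010, 1)),
     EddCoding(date(2010, 10, 8), CalendarQuarter(2010, 2))],
)
est = estimate_onset(rec)
print(est.onset, est.method.value)
```

prints `2010-01-01 edd_concordant`: both codings survive screening, they are
concordant, and 2010-10-08 minus 280 days is 2010-01-01, making the pregnancy
277 days long at birth.

The full pipeline from the shell:

```sh
gestbegin simulate --seed 7 --out cohort
gestbegin estimate --cohort cohort --out results
gestbegin validate --cohort cohort --estimates results/estimates.csv --out results
```

which prints

```
simulated 10000 pregnancies -> cohort
estimated 10000 pregnancies -> results
validation report -> results/validation_report.csv
```

`estimates.csv` carries one row per pregnancy with full provenance (method
branch, number of codings, discordance, exclusion reasons):

```
pregnancy_id,onset_date,method,resolved_edd,n_edds_total,n_edds_plausible,max_discordance_days,exclusion_reasons
P000000,2014-01-11,edd_concordant,2014-10-18,2,2,0,
P000001,2011-04-03,edd_concordant,2012-01-08,2,2,0,
```

and `validation_report.csv` holds the cohort statistics, e.g. for this seed:

```
stratum                          statistic             value     denominator
availability                     share_any_edd         0.8249    10000
availability                     share_all_concordant  0.8023    8249
pregnancy_length/term            median                276.0     6512
pregnancy_length/preterm         median                249.0     552
pregnancy_length/after_due_date  median                289.0     1185
```

— 82.5% of simulated pregnancies have at least one plausible EDD, and the
estimated pregnancy-length medians land on the class-specific lengths the
fallback constants are built from. Onset estimates in hand, gestational age
at any event date is `gestational_age_at(event_date, est.onset)`.

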