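# Methods

## The estimation problem

Claims databases record the date of a live birth and (in the German coding
system) the expected delivery date (EDD), but not the last menstrual period
(LMP) that defines gestational age. The EDD is coded in the outpatient
setting with calendar-quarter granularity — each entry is a date plus the
year/quarter in which it was coded — optionally, repeatedly, and sometimes
inconsistently. `gestbegin` estimates the LMP from these inputs with a
deterministic rule pipeline; there is no fitting or learned state anywhere.

Inputs are three tables per cohort: pregnancies (id, maternal age 12–50,
birth date, outcome class ∈ {preterm, term, after_due_date}), EDD codings
(id, EDD date, coding year+quarter), and exam events (id, date, kind ∈
{first_prenatal, antibody_screen, other}). Non-live-birth pregnancies are out
of scope: two of the screening criteria are undefined without a birth date.

## Screening

An EDD coding is discarded when any of these holds (criteria are evaluated
independently and every applicable reason is logged):

| criterion | rule | rationale |
|---|---|---|
| i | EDD < first day of coding quarter | a due date cannot predate its coding window |
| ii | EDD > last day of coding quarter + 365 d | too far ahead to be a genuine due date |
| iii-a | EDD − birth > 168 d (24 wk) | birth implausibly early vs. EDD |
| iii-b | birth − EDD > 21 d (3 wk) | birth implausibly late vs. EDD |
| iv | coded in birth quarter ∧ EDD = birth date | likely a transcribed known birth date |

All comparisons are strict, mirroring the "earlier than" / "more than"
phrasing of the rules: the exact boundary value survives. Criterion ii uses a
fixed 365-day year rather than a calendar-year rule so leap years cannot flip
a verdict; the constant is configurable and overrides are logged. Criterion
iv deliberately does **not** fire for an EDD equal to the birth date but coded
in an earlier quarter — that is a genuinely prophetic due date.

Readers reject (with per-row reasons, never silently): maternal age outside
12–50, codings stamped outside the birth quarter or the three preceding
quarters, exam events after the birth or more than 366 days before it, orphan
child rows, and malformed values. Rejected rows plus accepted rows always sum
to the input row count.

## Resolution and back-calculation

Among the plausible codings of one pregnancy (the excluded ones never vote),
the working EDD is: the date itself when there is one coding or all agree;
otherwise the mode of the multiset — multiplicity counts per coding record,
including identical duplicates within one quarter; when several dates tie at
maximal frequency (in particular when all codings are distinct), the
arithmetic mean of the tied dates. A half-day mean is rounded toward the
earlier date: a conservative choice (the true onset is at stake, and rounding
earlier never shifts an exposure window later than either tied candidate);
with two tied dates the midpoint is otherwise exact, and ties of more than
two dates resolve to a mean strictly between the extremes.

The onset is then `resolved EDD − 280 d`. With no plausible EDD, the fallback
subtracts the class-specific median pregnancy length observed under the EDD
method itself — 276 d (term), 249 d (preterm), 289 d (after due date) —
rather than the published 273/245-day constants, which were derived from a
different (Canadian) population; those remain available solely for the method
comparison, with 280 d for post-term births where the published method is
silent.

Provenance travels with every estimate: method branch (7 labels), resolved
EDD, total and plausible coding counts, maximal discordance in days, and the
distinct exclusion reasons encountered.

Gestational age at an event is `event − onset` in days; completed week *w*
spans days [7w, 7w+6] with day 0 = LMP. Under this convention "weeks 24–27"
= days 168–195, the first-prenatal window "day 28–56" is inclusive on both
ends, and ±1/±2 week widenings add 7/14 days on each side. The week
convention is a package choice; the source rules never state one.

## Validation statistics

All quantiles are inverted-ECDF (type-1) on integer day counts, so every
reported quantile is an observed data point and integer summary tables are
reproduced exactly; this also fixes tie-breaking. Denominators are explicit
in every output row; a share over an empty stratum is never reported (the
discordance quantile block is omitted when no pregnancy is discordant, and an
empty cohort is rejected).

Two analytic identities hold exactly per pregnancy and are asserted in tests:
`length = 280 + (birth − resolved EDD)` (linking the difference table to the
length table — a monotone shift, so it also links their medians), and
`onset_EDD − onset_median_length = (EDD − birth) − 7` for term births,
`− 35` for preterm, `± 0` for post-term. Sign conventions: birth − EDD
(negative = birth before due date); EDD-method onset − median-length onset
(negative = EDD method earlier).

The second antibody screening is evaluated on the chronologically second
antibody event, and only for pregnancies with at least two such events — a
lone event cannot be the *second* screening. The first prenatal examination
uses the earliest event of its kind. Implausibly early first-exam codes are
reported against both a day-20 (approximate nidation) and a day-8 threshold,
since either can be read as "before biological plausibility".

## Synthetic cohort generator

The generator emulates the claims structure the algorithm assumes, with
defaults set to the emulated study conditions: outcome-class mixture
0.068 / 0.793 / 0.139 (preterm / term / after due date); probability 0.176 of
no EDD coding; among pregnancies with codings, pattern mixture
0.061 / 0.809 / 0.131 (single / concordant multi / discordant multi,
renormalized); 2–4 codings for multi patterns; true LMP uniform over
2006–2015. Birth dates are `LMP + 280 + offset`, with the offset drawn per
class from a piecewise-linear inverse CDF through the observed
birth-minus-EDD quantile anchors at p = 0.05…0.95 (preterm −78…−20, term
−18…6, post-term 2…13), linearly extended 10 days beyond the outer anchors —
the least-assumption interpolant when only quantiles are known. Discordant
sets keep one coding at the true EDD and spread the others to a maximal
difference drawn from an inverse CDF through anchors (median 5 d, IQR 3–7,
5–95% 1–16), the spread split uniformly between earlier and later. Codings
are stamped uniformly into the quarters overlapping the pregnancy, never
after the birth quarter. Exam gestational ages are mixtures: first prenatal
76% uniform on days 28–56, remainder uniform on days 0–140; second antibody
74% uniform on days 168–195, remainder in ±4-week tails, with a first
antibody event uniform on days 63–112. An exam whose drawn gestational age
reaches the pregnancy length is not emitted (it could not have occurred);
this naturally yields preterm pregnancies with a single antibody event.

Identical parameters (including the mandatory seed) give byte-identical
CSVs. Each cohort carries a ground-truth table (true LMP, true EDD, birth
offset), making the generator the oracle for recovery tests: with the
discordant share at zero, the estimator must return the true LMP for every
pregnancy with at least one plausible EDD — and does, exactly.

What the generator does *not* emulate: the joint distribution of coding count
and coding quarter in real claims (unknown; quarters are stamped uniformly),
correlated misclassification of outcome classes, drug dispensations, multiple
gestations, and non-live-birth outcomes. Passing tests therefore demonstrate
the algorithm's internal correctness and calibration under these assumptions,
not the cohort-dependent percentages any real database would produce. A
deterministic adversarial fixture complements the sampler: hand-built records
pinning each screening criterion at ±1 day around its threshold and touching
all seven method branches.

## Problem sizes and numerical choices

Simulation-based checks run at n = 10,000 pregnancies (binomial 99%
confidence intervals at that size are roughly ±1 percentage point, tight
enough to detect miscalibration of any mixture weight); fixture-based checks
use 1–3 records. Calibration tests compare empirical quantiles to the anchors
within ±2 days, absorbing the rounding of interpolated offsets to integer
days. All dates are `datetime.date`; durations are exact integer day
arithmetic, so there is no floating-point tolerance anywhere in the algorithm
itself.

## Known limitations

* The quarter-stamping model can make a perfectly coded EDD implausible
  (e.g. a post-term birth whose coding lands in a birth quarter that opens
  after the EDD); such pregnancies legitimately fall back, which slightly
  depresses synthetic availability below 1 − p_no_edd.
* Constants are configurable but the validation suite's identities assume the
  default 280-day offset when quoting the ±7/±35-day method-comparison
  shifts.
* The exam-timing summaries evaluate events against the *estimated* onset;
  for fallback pregnancies the window shares therefore mix estimation error
  with scheduling variability, exactly as they would on real data.
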