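# Methods

## Scope and model

`psyrx` quantifies antipsychotic prescribing in an inpatient cohort along
three axes: dose intensity (PDD/DDD), regimen structure (antipsychotic
polypharmacy), and indication (off-label screening). The unit of analysis is
one admission per patient; inputs are three delimited tables (patients,
diagnoses, prescriptions) plus a DDD registry and an off-label policy table.

## ATC codes and the DDD registry

ATC codes are validated against the level grammar (letter, two digits, two
letters, two digits; prefixes of length 1/3/4/5 are accepted for group
queries) and upcased. Antipsychotic membership is `N05A` minus the `N05AN`
(lithium) subgroup: lithium shares the therapeutic subgroup but is excluded
from antipsychotic utilization analysis.

The registry keys entries by *(ATC, route, form)* because DDDs are
presentation-specific (oral risperidone 5 mg vs long-acting 2.7 mg; oral
paliperidone 6 mg vs long-acting 2.5 mg). The bundled default covers the 18
antipsychotic presentations of the reference utilization table shipped in
`psyrx/data/`; tiapride, marketed both orally and parenterally with one DDD
(400 mg), is stored once per route, giving 19 entries. Routes are assigned by
presentation (oral for standard tablets, injectable for depot forms), since
the reference table's own route annotations are internally inconsistent.
Registry files are delimited text with a header; unknown columns are ignored,
so the registry extends beyond antipsychotics without code changes. No ATC
index year is asserted: the registry is fixture-defined, not authoritative.

## Prescribed daily dose

Daily schedules convert as `dose_mg × times_per_day`; depot schedules as
`dose_mg ÷ interval_days` on calendar days, ignoring pharmacokinetics
(25 mg every 28 days → 0.89 mg/day; 100 mg every 28 days → 3.57 mg/day).
Within a prescription's inclusive date range a depot contributes its
uniform daily equivalent — equivalently, the mean of a ledger placing the
full dose at injection.

A patient's PDD for one presentation is computed on a per-day ledger:
overlapping same-presentation orders sum; the PDD is the mean over *exposed*
days (days with nonzero dose), not over the whole stay. Averaging over the
full admission would deflate the PDD below every dose actually prescribed,
turning a dose-intensity measure into a duration measure; exposed-days
averaging is therefore the package's documented convention. Date ranges are
inclusive at both ends (a one-day order has one exposed day). Dose titration
is represented as multiple consecutive orders; there is no intra-order taper
syntax.

## Utilization statistics

Per presentation: n (by default one count per patient-presentation exposure;
`count_mode="order"` counts raw orders instead), median and mean PDD, a 95%
CI, the mean PDD/DDD ratio, and the excessive-dose flag. Exposure counting is
the default because reference cohorts of this kind report ~1.7 prescriptions
per treated patient, consistent with exposures rather than order lines.

The CI is the t-interval `mean ± t(0.975, n−1)·sd/√n` with sample sd;
n = 1 and zero-variance samples collapse to a point interval. A normal-based
interval would be equally consistent with the degenerate published CIs; the
t-interval is the package's choice and is symmetric by construction.

Excessive dosing is `ratio > 1.5`, strict, evaluated on the unrounded ratio:
a presentation at exactly 1.50 is not excessive. Display rounding is half
away from zero (ratios and doses to 2 dp, percentages to 1 dp), applied only
at serialization and routed through the decimal representation so binary
float artifacts cannot flip a tie.

## Regimen classification

Antipsychotic polypharmacy is ≥2 distinct antipsychotic chemicals
(7-character ATC; oral + depot of one chemical count once — the APP
literature counts agents, not formulations; `count_presentations_separately`
overrides) active on the same calendar day. A depot order is active through
its entire injection interval. `min_overlap_days` (default 1) requires a
concurrency level to be sustained that many days before it counts, so
cross-taper handovers can be excluded. Sequential switching is monotherapy.
`antipsychotic_only` separately records whether antipsychotics were the
patient's only psychotropics, the alternative reading of "polytherapy".
Classification is invariant to prescription order and is property-tested
against a brute-force day-sweep oracle.

## Diagnoses, age bands, off-label policy

ICD-10 codes map to decade blocks of the F chapter: F00–F09 organic, F10–F19
substance use, F20–F29 schizophrenia/psychoses, F30–F39 mood, F40–F49
anxiety-related, F60–F69 personality; everything else (including non-F
chapters) is `other`. Age bands are half-open with boundaries ascending —
[18,35), [35,50), [50,65), [65,∞) — a convention the package must fix because
reporting tables in this field commonly print overlapping band labels (35
appearing in two columns).

Off-label status is data-driven: policy rows map an ATC prefix to the
diagnosis categories that license it, and a drug's licensed set is the union
over matching rows, which makes the off-label share monotone nonincreasing
as the policy grows. The shipped default licenses all antipsychotics for
psychotic disorders only; it is an editable surrogate for a jurisdictional
label database, not a regulatory source. A drug no row covers is flagged
(with a warning), never raised.

## Cohort reports

Table 1 (demographics × diagnosis) reports per-category n, cohort share,
within-category age-band and sex distributions, and Pearson chi-square P
values without continuity correction; each category is tested against the
rest of the cohort by default (a full-table variant is available, since
either reading is defensible). Expected cell counts below 5 trigger a
warning, not an alternative test. Comorbid patients contribute once to each
category they carry.

Table 2 assigns every patient to exactly one stratum: single-category
patients to the named category rows (unnamed ones to "Rest of the
diagnoses"), two-category patients to named unordered pairs, everything else
to "Other combinations"; columns are patients, antipsychotic users,
monotherapy and polypharmacy, with a totals row. Table 3 delegates to the
utilization summary, ordered by drug name.

## Synthetic cohorts

The generator emulates a brief psychiatric inpatient unit: ~353 patients,
diagnosis-category mix and per-category antipsychotic-use probabilities taken
from the single-diagnosis strata of the reference cohort (schizophrenia ≈ 1.0,
mood ≈ 0.74, substance use 0.5, personality ≈ 0.57, anxiety ≈ 0.21),
comorbidity probability 0.31 (use follows the primary category), polypharmacy
share 0.368 among users, stays of 7–30 days, and lognormal daily doses with
mean `target_ratio × DDD` (σ = 0.4; doses are positive and right-skewed, as
reference tables where means exceed medians suggest). Drug choice follows the
reference prescription frequencies; depot presentations are dosed every 28
days; 70% of patients also receive one non-antipsychotic psychotropic
(benzodiazepine, SSRI or valproate from a small built-in list) so the
antipsychotic-only flag is exercised. Under this profile the overall
antipsychotic-use rate is ≈ 0.73 — the rate implied by the single-diagnosis
strata — slightly above the reference cohort's overall 61.5%, which is pulled
down by zero-use catch-all strata whose composition is not reconstructible;
tests that recover a target overall rate set a flat use probability instead.
Same seed, same bytes; parameter recovery (use and polypharmacy
probabilities within 99% binomial intervals at n = 5000, dose-ratio recovery
within ±0.1) is part of the test suite.

Two deterministic reconstruction cohorts accompany the generator. The
utilization fixture rebuilds, per drug, a positive PDD sample matching the
published n, median and mean exactly (middle order statistics pinned at the
median, one tail shifted to hit the mean), so the analyzer reproduces every
published ratio; published CIs are not reproducible from summary statistics
except the degenerate n ≤ 2 rows, which do match. The regimen fixture
rebuilds the diagnosis-by-regimen cross-tabulation; one published stratum
prints more users (9) than patients (7), an inconsistency in the source
table, so that stratum is built with 9 patients — column totals (217 users,
137 monotherapy, 80 polypharmacy) and per-row conservation are preserved
while the cohort totals 355 rather than 353. Two published percentages
(63.2%, 36.8%) disagree with their own printed fractions by 0.1 points;
tests pin the recomputed values (63.1%, 36.9%) and document the printed ones.

What passing tests on synthetic data do **not** show: real prescribing has
dose titration, informative missingness, route switches mid-stay and
diagnosis revisions, none of which the generator emulates; results on real
extracts depend on the registry and policy tables supplied.

## Numerical and degenerate-input conventions

Zero-denominator percentages return NaN sentinels rather than raising; empty
prescription lists yield a zero-PDD exposure flagged `no_exposure`; drugs
with zero users are omitted from per-drug shares; categories or strata with
zero patients are omitted from report bodies (totals rows always appear).
Problem sizes in the shipped checks — 500 randomized concurrency instances,
5000-patient recovery cohorts — keep the full suite in a few tens of seconds.

## Limitations

No chlorpromazine-equivalent conversion between chemicals, no
pharmacokinetic depot modelling, no loading-dose regimens, no DDD units
other than mg/day, no longitudinal linkage across admissions, and the
off-label policy is indicative, not regulatory.
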