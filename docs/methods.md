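# Methods

## Scope and model

`respcohort` implements a harmonised curation procedure for building
asthma, COPD and ILD cohorts from primary-care extracts that differ in
identifier scope, birth-date granularity, coding systems and
prescription semantics. The three supported *dialects* are abstract
profiles, not database connectors: `cprd_like` (per-registration
identifiers, year of birth, medcode/SNOMED clinical coding, dm+d-style
product codes, issued prescriptions, events usable only inside the
registration window), `sail_like` (per-person identifier, week of
birth, Read V2 throughout, issued prescriptions, no drug codes for
products launched after the 2016 Read deprecation) and `dataloch_like`
(per-person identifier, month+year of birth, Read events, BNF-coded
dispensed prescriptions available from 2009). No licensed dataset is
read; bundles in the documented CSV layout — typically produced by the
built-in generator — are the only input.

## Cohort construction

Inclusion requires recorded sex (male/female), at least one valid
disease event on or before the latest event date (default 2019-12-31),
and follow-up reaching the study era (any time from 2004-01-01).
An event is valid when it lies within the patient's lifetime judged
against the *imputed* birth date (what the source could observe), on
or before the latest event date, and at or above the disease minimum
age (COPD 35, ILD 40, asthma none). Exclusions are applied in a fixed
order — sex, valid event, study-era overlap, dialect quality flags —
and each removed patient is tallied under the first criterion that
removed them, so included + excluded always equals the input count.
"Registered from 2004" is implemented as overlap: the follow-up end
must fall on or after 2004-01-01.

Follow-up starts at the registration start (per-registration sources)
or the minimum registration start (per-person sources); it ends at the
earliest of death, registration end and the last practice collection
date, or of death, maximum registration end and the extraction date,
respectively. An open registration contributes no end candidate.

Two diagnosis dates are derived. The earliest mention is the minimum
valid event date over all classifications; the date of incidence is
the minimum over incident-classified codes, set to missing whenever the
earliest mention falls within the first year of registration — chronic
disease coded shortly after joining a practice is usually prevalent
disease entering a fresh record. "First year" is the half-open
interval `[followup_start, followup_start + 1 calendar year)`; the
boundary day itself is outside the first year. In per-registration
sources each identifier is assessed independently, which is why the
masking rule matters most there.

ILD members carry independent subtype flags (IPF broad/narrow,
exposure-related, autoimmune-related, treatment-related, other); a
narrow-definition IPF code also sets the broad flag, and no mutually
exclusive final label is ever assigned.

## Demographic harmonisation

Birth dates are imputed deterministically: 1 July of the birth year;
the Monday of the ISO birth week (week-of-birth input is interpreted as
an ISO week); the 1st of the birth month. Death dates come from the
primary mortality register, falling back to the register's registration
date when the death date itself is missing; in the per-registration
dialect, deaths after the primary register's coverage end (default
2021-03-31) are taken from the internally derived date, and an internal
date *inside* the coverage window without a register record is not
trusted. Deprivation quintiles are reported only as descriptive labels
because IMD numbers quintile 1 as least deprived while WIMD/SIMD number
it as most deprived; the mapping is an order-reversing bijection per
scheme. Ethnicity is resolved from GP codes first and hospital codes
only when the GP record is silent, taking the modal harmonised category
with a most-recent-record tie-break; the broad scheme has six levels
(White, Black, Asian, Mixed, Other, Missing) — Missing completes the
six. A codelist can carry all four categorisation schemes as extra CSV
columns; otherwise a fixed harmonised→scheme table is used.

## Clinical measures

All cleaning restricts values to configurable plausible ranges (adult
BMI 10–80 kg/m², height 1.0–2.2 m, weight 20–250 kg, FEV1 0.1–8 L,
FEV1 % predicted 10–150 %), and every rejected value is logged with the
rule that removed it. Smoking: same-day conflicts resolve by
precedence current > ex > never, and a "never" after any ever-smoker
observation is re-coded to "ex". BMI: recorded values are preferred;
on days with a usable weight but no recorded BMI, weight / height² is
derived using the same-day else nearest prior height — except in the
dispensed-prescription dialect, which uses recorded BMI only.
Spirometry: the highest same-day FEV1 is kept; a GP-entered percent-
predicted from the same day is preferred, otherwise the value is
derived as FEV1 / FEV1_predicted × 100 with the ERS 1993 adult
equations (male 4.30·H − 0.029·A − 2.49; female 3.95·H − 0.025·A − 2.60,
litres). The equations are deliberately applied to all ages and
ethnic groups; they require height, so the nearest prior height
measurement is used and derivation is skipped (percent-predicted left
missing) when none exists or sex is unrecorded. Coefficients and
ranges live in configuration so they can be aligned with other
published tables. GOLD stages percent-predicted with boundaries
assigned to the milder stage (80 → 1, 50 → 2, 30 → 3), applied
regardless of bronchodilation status. Window selection for reporting
takes the most recent observation with both bounds inclusive.

## Medications

Prescriptions are classified by codelist lookup in their own coding
system, with one-hop mapping translations (plus the dm+d → ATC → Read
two-hop route) tried for codes absent from the dialect's lists.
Combination flags are established from same-day components for the
combinations that need it — triple therapy (LABA+LAMA+ICS), LABA-LAMA
and SABA-SAMA — counting components contributed by combination
products (a LABA-ICS product supplies LABA and ICS). LABA-ICS itself
is never inferred from components: it predates the Read deprecation
and always has its own codes, and two separate inhalers are not a
fixed-dose combination. Detection runs in every dialect so flags stay
comparable; note that a Read-coded source necessarily also records the
component categories of a combination product, so *single*-category
counts (LABA, LAMA, ICS) can run higher there than in product-coded
sources for the same prescribing — combination flags, not component
counts, are the cross-dialect comparable quantity. Annual usage counts
distinct members with at least one flagged patient-day per category in
the year; PDE4 inhibitors and antibiotics are reported for COPD
cohorts only, with the antibiotics category scoped by whichever
codelist is supplied.

## Synthetic generator: what it emulates

The generator draws a latent population with exact dates — birth
(uniform 1920–2017), death (age ~N(81, 12), censored at the 2022-03-07
extraction horizon), sex (0.5 % unrecorded), disease status
(prevalences asthma 10 %, COPD 4 %, ILD 1 %), onset ages (asthma
N(8, 9) truncated at ≥2 years; COPD N(65, 10) on [40, 90]; ILD
N(72, 8) on [45, 92]), practice moves (20 % of persons, 1–3 moves at
uniform adult ages, registrations contiguous), smoking and BMI
trajectories with GP observation schedules from 2002, COPD spirometry
trajectories, one height measurement, ethnicity codes, deprivation on
a canonical 1–5 scale, and drug regimens with ~quarterly prescriptions
from 2006 (post-2016 combination products from 2017, their UK approval
era). Onset truncation keeps a ≥2-year margin above the COPD/ILD age
thresholds so that birth-imputation error (≤366 days) cannot flip a
threshold decision — exact truth recovery is then a property of the
pipeline, not of rounding luck. For the late-onset diseases the
prevalence parameter is the risk among persons whose observed lifetime
reaches the onset-age range; persons born too recently to reach it
cannot be cases, so the empirical population prevalence of COPD/ILD
sits below the nominal parameter while the asthma parameter reproduces
a binomial count.

Two generator behaviours mirror documented recording practice and are
load-bearing for cross-dialect comparisons: when a patient joins a new
practice, a pre-existing diagnosis is re-recorded early in the fresh
registration with probability `rerecord_prob` (default 1.0 — prevalent
disease entering a new record as if incident), and a new-patient
health check records smoking status and BMI shortly after joining.
With re-recording on, all three dialects recover the true diseased
population exactly at zero noise; with it off, per-registration
identifier fragmentation visibly drops movers whose diagnosis sits in
a pre-2004 registration — every such loss is attributable to a named
exclusion criterion. Noise knobs (per-variable Bernoulli record drops,
smoking miscoding, BMI keystroke outliers, missing register death
dates, invalid quality flags) all default to 0; they exist to exercise
the cleaning and fallback paths, not to model any measured error rate,
since no quantitative noise description was available to calibrate
against.

What the generator does *not* emulate: realistic disease natural
history or UK-calibrated prevalence by age, secondary-care episodes
beyond a minimal ethnicity-bearing hospital table, free text, coding
drift over time, and correlated (non-independent) missingness.
Passing recovery tests therefore demonstrate that the curation logic
is faithful to its rules, not that the rules are robust to every
real-world recording pathology.

## Numerical and design choices

- Ages are completed years against the imputed birth date; the
  vectorised and scalar implementations are cross-checked by
  brute-force oracles in the tests.
- One year after registration is a calendar-year addition; 29 February
  maps to 28 February.
- Same-day ties: highest FEV1, highest percent-predicted, smoking
  precedence current > ex > never.
- Derived BMI uses unrounded floats, so a weight-rendered observation
  reproduces the latent BMI to machine precision.
- In per-registration bundles, each identifier is assessed
  independently; a person's cohort membership is the union over their
  identifiers. Person-level comparisons across dialects go through the
  truth manifest.
- The age-at-first-mention table in a per-registration dialect is
  expected to shift older than in per-person dialects: re-recorded
  prevalent disease in later registrations adds adult first mentions.
  The imputation-tolerance agreement claim (±1 year) therefore applies
  to person-level first mentions, checked on non-movers.
- Empty cohorts describe to zero-count tables rather than erroring;
  every frequency table carries an explicit Missing row so counts
  conserve the cohort size.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use a 10,000-person
population for end-to-end recovery and concordance, 1,000 randomized
patients for the diagnosis-date oracle, 10,000 random birth dates per
dialect for imputation bounds, and a 6,000-person COPD-enriched
population (yielding ~700 triple-therapy users) for combination-flag
equivalence. Smaller fixtures (600 persons) back the unit tests.

## Known limitations

- The shipped vocabulary and mapping are a desk-scale synthetic
  universe; real codelists and licensed dictionary tables plug in
  through the same CSV schemas but are not redistributed.
- Regions are pass-through labels; no geography below region level.
- No FVC/ratio airflow-obstruction confirmation, pack-years, dose or
  adherence modelling, or child growth-reference BMI.
- CPRD-style "acceptable patient" and CHI validity checks are modelled
  as boolean flags on synthetic records, not recomputed.
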