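# respcohort

A harmonised EHR phenotyping toolkit for chronic respiratory disease.
It builds asthma, COPD and interstitial lung disease (ILD) cohorts with
consistently derived variables from three differently-coded styles of
UK primary-care extract, and validates every curation stage on a
built-in synthetic multi-dialect population with known ground truth.

## The problem

UK primary-care databases record the same clinical reality in
structurally different ways. One source issues a fresh patient
identifier per GP registration, gives only the year of birth, codes
events with medcode/SNOMED-CT identifiers and drugs with dm+d-style
product codes; another uses one identifier per person, week of birth
and Read V2 codes throughout; a third uses month+year of birth, Read
events and BNF-coded *dispensed* prescriptions available only from
2009. Without harmonised derivation rules, incidence, prevalence and
covariate estimates diverge across sources for purely structural
reasons. `respcohort` implements those rules as a reusable library:

- **Codelist registry** — validated codelists (incident/prevalent
  classification per code) and cross-terminology mappings
  (medcode ↔ SNOMED ↔ Read; dm+d → BNF; dm+d → ATC → Read).
- **Cohort builder** — common inclusion criteria (recorded sex, ≥1
  valid disease event on or before 2019‑12‑31, alive and registered
  any time from 2004‑01‑01; minimum event age 35 for COPD, 40 for
  ILD), ordered exclusion tallies, follow-up windows per dialect, and
  two diagnosis dates: *earliest mention* (first valid code) and
  *date of incidence* (first incident code, blanked when the earliest
  mention falls within the first year of registration).
- **Demographics** — deterministic birth-date imputation (1 July of
  the birth year / Monday of the ISO birth week / 1st of the birth
  month), death-date resolution with register fallbacks, deprivation
  quintiles harmonised to descriptive labels (IMD counts 1 = least
  deprived; WIMD/SIMD count 1 = most deprived), GP-first ethnicity
  with hospital top-up.
- **Clinical measures** — cleaned longitudinal smoking, BMI and
  spirometry records. FEV1 % predicted is derived where the GP entered
  none, using the ERS 1993 adult reference equations
  (male `4.30·H − 0.029·A − 2.49` L; female `3.95·H − 0.025·A − 2.60` L,
  height H in metres, age A in years), and GOLD-staged
  (≥80 % → 1, 50–79 → 2, 30–49 → 3, <30 → 4).
- **Medications** — classification into SABA/SAMA/LABA/LAMA/ICS,
  fixed-dose combinations, OCS, triple therapy, theophylline, PDE4
  inhibitors and antibiotics, with same-day component detection for
  post-2016 combination inhalers that have no Read code.
- **Reporting** — cohort description at an index date with a 5-year
  measurement lookback, 2019 medication usage, and the
  age-at-first-mention distribution by sex (capped at 93 years).
- **Synthetic EHR generator** — a latent population with exact truth
  (disease onset, trajectories, practice moves) rendered into any
  dialect, with a truth manifest for recovery testing.

## Worked example

```python
from respcohort.cohort import CohortSpec, apply_cohort_criteria
from respcohort.dialects import PROFILES
from respcohort.synth import GenerationParams, generate_population, render_dialect, vocab

params = GenerationParams(n=2000)
population = generate_population(params, seed=7)
codelists = vocab.default_codelists()
bundle, manifest = render_dialect(
    population, PROFILES["sail_like"], codelists,
    vocab.default_mapping(), seed=8, params=params)

spec = CohortSpec.for_disease("copd")          # minimum event age 35
result = apply_cohort_criteria(bundle, spec, codelists["copd"], PROFILES["sail_like"])
print(len(result.members), result.tally)
recovered = manifest.persons_of(result.patient_ids)
expected = manifest.expected_person_ids("copd", min_event_age_years=35)
print(recovered == expected)
```

prints

```
44 {'sex_not_male_female': 14, 'no_valid_disease_event': 1935,
    'not_alive_and_registered_from_2004': 7, 'failed_dialect_quality_criteria': 0}
True
```

— 44 COPD patients included, every one of the 2,000 input patients
accounted for by the inclusion count plus the ordered exclusion tally,
and the recovered membership identical to the generator's ground
truth. The `examples/` directory holds one short script per
capability (bundle generation, cohort building, measure cleaning,
combination detection, cohort description), each printing the numbers
it computes and what they mean. A thin CLI wraps the same workflow:
`respcohort generate`, `respcohort build-cohort`, `respcohort describe`.

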