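"""Clean raw smoking, BMI and spirometry events for one patient.

Shows the main cleaning rules in action: a 'never smoker' recorded
after a current-smoker code is re-coded to ex-smoker; BMI is derived
from same-day weight and a prior height when no recorded BMI exists;
the highest same-day FEV1 is kept and FEV1 % predicted is derived from
the ERS 1993 reference equation when the GP entered none, with the
GOLD stage attached.
"""

from datetime import date

import pandas as pd

from respcohort.dialects import CPRD_LIKE
from respcohort.codelists import System
from respcohort.measures import (
    build_bmi_record,
    build_smoking_record,
    build_spirometry_record,
    predict_fev1,
)
from respcohort.synth import vocab

codelists = vocab.default_codelists()
MC = System.MEDCODE


def ev(rows, concept, with_value=True):
    return pd.DataFrame(
        [(d, vocab.clinical_code(concept, MC), "medcode", v) for d, v in rows],
        columns=["date", "code", "system", "value"],
    )


smoking_events = pd.concat([
    ev([("2008-01-10", None)], "smok_current"),
    ev([("2013-06-01", None)], "smok_never"),   # contradicts the 2008 record
])
smoking = build_smoking_record(smoking_events, codelists["smoking"])
print("smoking record (never-after-current re-coded to ex):")
print(smoking.to_string(index=False), "\n")

bmi, drops = build_bmi_record(
    ev([("2015-03-01", 27.5), ("2017-02-01", 412.0)], "obs_bmi"),  # 412 is a typo
    ev([("2016-05-01", 80.0)], "obs_weight"),
    ev([("2015-03-01", 1.80)], "obs_height"),
    birth_date=date(1960, 7, 1),
    profile=CPRD_LIKE,
)
print("BMI record (weight 80 kg / height 1.80 m derives 24.69):")
print(bmi.to_string(index=False))
print("dropped values:\n", drops.to_string(index=False), "\n")

spiro_events = pd.concat([
    ev([("2016-09-01", 1.9), ("2016-09-01", 2.1)], "obs_fev1"),  # same-day pair
])
heights = pd.DataFrame({"date": ["2015-03-01"], "value": [1.75]})
spiro, _ = build_spirometry_record(
    spiro_events, sex="male", birth_date=date(1960, 7, 1),
    codelist=codelists["spirometry"], height_record=heights,
)
print("spirometry record (highest same-day FEV1, derived % predicted, GOLD):")
print(spiro.to_string(index=False))
predicted = predict_fev1("male", 56, 1.75)
print(f"\ncheck: predicted FEV1 for a 56-year-old 1.75 m male is "
      f"{predicted:.3f} L, so 2.1 L is {2.1 / predicted * 100:.1f}% predicted.")
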