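"""Classify prescriptions into drug categories and detect combination
therapy from same-day components.

Post-2016 combination inhalers have no Read code, so a Read-coded
source sees only the component drugs; flagging LAMA+LABA+ICS on the
same day recovers the triple-therapy signal that a product-coded
source gets from a single code.
"""

from respcohort.codelists import System
from respcohort.medications import classify_prescription, flag_same_day_combinations
from respcohort.synth import vocab

codelists = vocab.default_codelists()
mapping = vocab.default_mapping()
meds = codelists["medication"]

product = vocab.drug_code("triple_combo", System.DMD)
print(f"product-coded route: dm+d code {product!r} ->",
      classify_prescription(product, System.DMD, meds))

read_codes = [vocab.drug_code(k, System.READ_V2)
              for k in ("salmeterol", "tiotropium", "beclometasone")]
day_categories = set()
for code in read_codes:
    day_categories |= classify_prescription(code, System.READ_V2, meds)
print(f"Read-coded route: same-day components {read_codes} -> {sorted(day_categories)}")
flagged = flag_same_day_combinations(day_categories)
print("after same-day combination detection:", sorted(flagged))

print("\nBoth routes flag triple_therapy for the same patient-day, so "
      "medication usage stays comparable across dialects.")
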