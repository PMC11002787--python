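"""Asthma/COPD medication classification and combination detection.

Prescriptions are classified into the standard respiratory drug
categories (SABA, SAMA, LABA, LAMA, ICS, fixed-dose combinations, OCS,
triple therapy, theophylline, PDE4 inhibitors and antibiotics — the
last two relevant to COPD cohorts only).  In Read-coded sources the
post-2016 fixed-dose combination inhalers (LABA-LAMA, triple therapy)
have no drug code of their own, so combination use is additionally
detected from component drugs prescribed on the same day: a patient-day
carrying LAMA, LABA and ICS (counting components contributed by
combination products) is flagged as triple therapy.  Combination
detection runs in every dialect so the flags stay comparable.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .codelists import Codelist, CodeMapping, System, translate_code
from .dialects import DialectProfile, IdScope

__all__ = [
    "DRUG_CATEGORIES",
    "COPD_ONLY_CATEGORIES",
    "COMBINATION_COMPONENTS",
    "classify_prescription",
    "flag_same_day_combinations",
    "build_medication_flags",
    "annual_category_usage",
]

#: The drug categories recorded per patient-day.
DRUG_CATEGORIES = (
    "SABA",
    "SAMA",
    "LABA",
    "LAMA",
    "ICS",
    "SABA_SAMA",
    "LABA_LAMA",
    "LABA_ICS",
    "OCS",
    "triple_therapy",
    "theophylline",
    "PDE4",
    "antibiotics",
)

COPD_ONLY_CATEGORIES = frozenset({"PDE4", "antibiotics"})

#: Components contributed by fixed-dose combination categories, used
#: when testing whether a patient-day satisfies a combination rule.
COMBINATION_COMPONENTS: Mapping[str, frozenset[str]] = {
    "SABA_SAMA": frozenset({"SABA", "SAMA"}),
    "LABA_LAMA": frozenset({"LABA", "LAMA"}),
    "LABA_ICS": frozenset({"LABA", "ICS"}),
    "triple_therapy": frozenset({"LABA", "LAMA", "ICS"}),
}

#: Combinations established from same-day components.  LABA-ICS predates
#: the 2016 Read-code deprecation and always has its own drug codes, so
#: it is never inferred from components (separate LABA and ICS inhalers
#: are not a fixed-dose combination).
DETECTED_COMBINATIONS = ("SABA_SAMA", "LABA_LAMA", "triple_therapy")


def _category_index(drug_codelists: Codelist | Iterable[Codelist]):
    """(code, system) -> set of category labels across the codelists."""
    if isinstance(drug_codelists, Codelist):
        drug_codelists = [drug_codelists]
    index: dict[tuple[str, System], set[str]] = {}
    for codelist in drug_codelists:
        for entry in codelist:
            if entry.category:
                index.setdefault((entry.code, entry.system), set()).add(entry.category)
    return index


def classify_prescription(
    code: str,
    system: System | str,
    drug_codelists: Codelist | Iterable[Codelist],
    mapping: CodeMapping | None = None,
) -> set[str]:
    """All drug categories whose codelists contain the (translated) code.

    The code is first looked up directly in its own system; when absent
    and a mapping is supplied, one-hop translations into every other
    system are tried (the dm+d → ATC → Read chain is attempted as the
    two-hop composition).  An empty set means the code matched nothing —
    which for post-2016 combination inhalers in Read-coded sources is
    expected, and is why same-day component matching exists.
    """
    system = System(system)
    index = _category_index(drug_codelists)
    found = set(index.get((code, system), ()))
    if found or mapping is None:
        return found
    candidates: set[tuple[str, System]] = set()
    for target in System:
        if target is system:
            continue
        for translated in translate_code(code, system, target, mapping):
            candidates.add((translated, target))
    if system is System.DMD:  # two-hop product → ATC → Read route
        for atc in translate_code(code, System.DMD, System.ATC, mapping):
            for read in translate_code(atc, System.ATC, System.READ_V2, mapping):
                candidates.add((read, System.READ_V2))
    for key in candidates:
        found |= index.get(key, set())
    return found


def flag_same_day_combinations(day_categories: set[str]) -> set[str]:
    """Augment one patient-day's categories with combination flags.

    Combination products contribute their components (a LABA_ICS
    prescription supplies both LABA and ICS) before testing each rule:
    triple_therapy when LAMA, LABA and ICS are all present; LABA_LAMA
    when LABA and LAMA are; SABA_SAMA when SABA and SAMA are.  Original
    flags are retained; LABA_ICS is never inferred from components.
    """
    components = set(day_categories)
    for category in day_categories:
        components |= COMBINATION_COMPONENTS.get(category, frozenset())
    augmented = set(day_categories)
    for combo in DETECTED_COMBINATIONS:
        if COMBINATION_COMPONENTS[combo] <= components:
            augmented.add(combo)
    return augmented


def build_medication_flags(
    prescriptions: pd.DataFrame,
    drug_codelists: Codelist | Iterable[Codelist],
    mapping: CodeMapping | None = None,
) -> pd.DataFrame:
    """Classify a prescriptions table into per-patient-day category flags.

    ``prescriptions`` needs columns patient_id, date, code, system.
    Returns a long frame (patient_id, date, category) with one row per
    flagged category per patient-day, combination flags included.
    """
    index = _category_index(drug_codelists)
    if len(prescriptions) == 0:
        return pd.DataFrame(columns=["patient_id", "date", "category"])
    # classify distinct codes once, then join back
    codes = prescriptions[["code", "system"]].drop_duplicates()
    classified = {
        (row.code, row.system): classify_prescription(
            str(row.code), row.system, drug_codelists, mapping
        )
        for row in codes.itertuples(index=False)
    }
    rows = []
    frame = prescriptions.copy()
    frame["date"] = pd.to_datetime(frame["date"])
    grouped = frame.groupby(["patient_id", "date"], sort=False)
    for (patient_id, day), group in grouped:
        categories: set[str] = set()
        for row in group.itertuples(index=False):
            categories |= classified[(row.code, row.system)]
        if not categories:
            continue
        for category in flag_same_day_combinations(categories):
            rows.append((patient_id, day, category))
    return pd.DataFrame(rows, columns=["patient_id", "date", "category"])


def annual_category_usage(
    prescription_flags: pd.DataFrame,
    cohort: pd.DataFrame,
    year: int,
    profile: DialectProfile | None = None,
    registrations: pd.DataFrame | None = None,
    copd_cohort: bool = False,
) -> dict[str, int]:
    """Number of distinct cohort members with >=1 flagged patient-day
    per category in the given calendar year.

    ``cohort`` needs a patient_id column.  In per-registration dialects
    each identifier's prescriptions only count inside its own
    registration window (pass ``registrations`` [patient_id, start,
    end]).  PDE4 and antibiotics are reported only for COPD cohorts.
    A patient counts once per category regardless of prescription count.
    """
    categories = [
        c for c in DRUG_CATEGORIES if copd_cohort or c not in COPD_ONLY_CATEGORIES
    ]
    counts = {c: 0 for c in categories}
    if len(prescription_flags) == 0 or len(cohort) == 0:
        return counts
    flags = prescription_flags.copy()
    flags["date"] = pd.to_datetime(flags["date"])
    flags = flags[flags["date"].dt.year == year]
    flags = flags[flags["patient_id"].isin(set(cohort["patient_id"]))]
    if (
        profile is not None
        and profile.patient_id_scope is IdScope.PER_REGISTRATION
        and registrations is not None
        and len(registrations)
    ):
        regs = registrations.copy()
        regs["start"] = pd.to_datetime(regs["start"])
        regs["end"] = pd.to_datetime(regs["end"])
        merged = flags.merge(regs, on="patient_id", how="left")
        in_window = (merged["date"] >= merged["start"]) & (
            merged["end"].isna() | (merged["date"] <= merged["end"])
        )
        flags = merged[in_window][["patient_id", "date", "category"]]
    per_category = flags.groupby("category")["patient_id"].nunique()
    for category, n in per_category.items():
        if category in counts:
            counts[category] = int(n)
    return counts
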