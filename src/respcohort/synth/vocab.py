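"""The synthetic code universe.

A desk-scale stand-in for the licensed terminology dictionaries: every
synthetic clinical concept has a medcode-style, SNOMED-style and Read-
style code; every synthetic drug has a dm+d-style product code, a BNF
code, an ATC code and — unless it postdates the 2016 Read-code
deprecation — a Read code.  The cross-terminology mapping mirrors the
real translation routes (medcode ↔ SNOMED/Read; dm+d → BNF; dm+d → ATC
→ Read), with the ATC → Read rows deliberately absent for post-2016
combination inhalers.

Codelists built here follow the standard CSV interchange schema and can
be written to disk with :func:`write_default_files`, so the same loader
used for real published codelists exercises them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from ..codelists import (
    CodeEntry,
    Codelist,
    CodeMapping,
    Purpose,
    System,
    write_codelist,
    write_mapping,
)

__all__ = [
    "DrugConcept",
    "DRUGS",
    "DISEASES",
    "ILD_SUBTYPE_OF",
    "clinical_code",
    "drug_code",
    "default_codelists",
    "default_mapping",
    "write_default_files",
]

DISEASES = ("asthma", "copd", "ild")


def clinical_code(concept: str, system: System) -> str:
    """Dialect-system code string for a synthetic clinical concept."""
    prefix = {System.MEDCODE: "m", System.SNOMED_CONCEPT: "sn", System.READ_V2: "r"}[system]
    return f"{prefix}_{concept}"


# ---------------------------------------------------------------- diagnoses

#: concept -> (disease, diagnostic?, description).  Diagnostic codes are
#: incident+prevalent; management codes prevalent only.
_DIAGNOSIS_CONCEPTS: dict[str, tuple[str, bool, str]] = {
    "asthma_dx1": ("asthma", True, "Asthma"),
    "asthma_dx2": ("asthma", True, "Late-onset asthma"),
    "asthma_dx3": ("asthma", True, "Allergic asthma"),
    "asthma_rev": ("asthma", False, "Asthma annual review"),
    "asthma_mon": ("asthma", False, "Asthma monitoring"),
    "copd_dx1": ("copd", True, "Chronic obstructive pulmonary disease"),
    "copd_dx2": ("copd", True, "Emphysema"),
    "copd_dx3": ("copd", True, "Chronic bronchitis with obstruction"),
    "copd_rev": ("copd", False, "COPD annual review"),
    "copd_mon": ("copd", False, "COPD monitoring"),
    "ild_ipf_narrow": ("ild", True, "Idiopathic pulmonary fibrosis"),
    "ild_ipf_broad": ("ild", True, "Pulmonary fibrosis"),
    "ild_hp": ("ild", True, "Hypersensitivity pneumonitis"),
    "ild_pneumoconiosis": ("ild", True, "Pneumoconiosis"),
    "ild_sarcoid": ("ild", True, "Pulmonary sarcoidosis"),
    "ild_ra": ("ild", True, "Rheumatoid lung disease"),
    "ild_drug": ("ild", True, "Drug-induced interstitial lung disease"),
    "ild_other": ("ild", True, "Interstitial lung disease NOS"),
    "ild_rev": ("ild", False, "ILD review"),
}

#: ILD diagnostic concept -> subtype flag category.
ILD_SUBTYPE_OF: dict[str, str] = {
    "ild_ipf_narrow": "ipf_narrow",
    "ild_ipf_broad": "ipf_broad",
    "ild_hp": "exposure_related",
    "ild_pneumoconiosis": "exposure_related",
    "ild_sarcoid": "autoimmune_related",
    "ild_ra": "autoimmune_related",
    "ild_drug": "treatment_related",
    "ild_other": "other",
}


def diagnostic_concepts(disease: str) -> list[str]:
    return [c for c, (d, dx, _) in _DIAGNOSIS_CONCEPTS.items() if d == disease and dx]


def management_concepts(disease: str) -> list[str]:
    return [c for c, (d, dx, _) in _DIAGNOSIS_CONCEPTS.items() if d == disease and not dx]


# ------------------------------------------------------------------- drugs


@dataclass(frozen=True)
class DrugConcept:
    key: str
    category: str
    description: str
    components: tuple[str, ...] = ()  # keys of component drugs (combinations)
    post_2016: bool = False  # no Read code in Read-coded sources


DRUGS: dict[str, DrugConcept] = {
    d.key: d
    for d in (
        DrugConcept("salbutamol", "SABA", "Salbutamol 100micrograms inhaler"),
        DrugConcept("ipratropium", "SAMA", "Ipratropium bromide inhaler"),
        DrugConcept("salmeterol", "LABA", "Salmeterol 25micrograms inhaler"),
        DrugConcept("tiotropium", "LAMA", "Tiotropium 18micrograms capsules"),
        DrugConcept("beclometasone", "ICS", "Beclometasone 200micrograms inhaler"),
        DrugConcept(
            "saba_sama_combo",
            "SABA_SAMA",
            "Salbutamol/ipratropium combination inhaler",
            components=("salbutamol", "ipratropium"),
        ),
        DrugConcept(
            "laba_ics_combo",
            "LABA_ICS",
            "Salmeterol/fluticasone combination inhaler",
            components=("salmeterol", "beclometasone"),
        ),
        DrugConcept(
            "laba_lama_combo",
            "LABA_LAMA",
            "Umeclidinium/vilanterol combination inhaler",
            components=("salmeterol", "tiotropium"),
            post_2016=True,
        ),
        DrugConcept(
            "triple_combo",
            "triple_therapy",
            "Fluticasone/umeclidinium/vilanterol triple inhaler",
            components=("salmeterol", "tiotropium", "beclometasone"),
            post_2016=True,
        ),
        DrugConcept("prednisolone", "OCS", "Prednisolone 5mg tablets"),
        DrugConcept("theophylline", "theophylline", "Theophylline m/r tablets"),
        DrugConcept("roflumilast", "PDE4", "Roflumilast 500micrograms tablets"),
        DrugConcept("azithromycin", "antibiotics", "Azithromycin 250mg capsules"),
    )
}


def drug_code(key: str, system: System) -> str | None:
    """Drug code string per system; None where the system has no code
    for this drug (post-2016 drugs in Read)."""
    drug = DRUGS[key]
    if system is System.READ_V2:
        return None if drug.post_2016 else f"y_{key}"
    prefix = {System.DMD: "d", System.BNF: "b", System.ATC: "atc"}[system]
    return f"{prefix}_{key}"


# ------------------------------------------------- measures and categories

_SMOKING_CONCEPTS = {
    "smok_never": "never",
    "smok_current": "current",
    "smok_ex": "ex",
}

_BMI_CONCEPTS = {"obs_bmi": "bmi", "obs_weight": "weight", "obs_height": "height"}

_SPIRO_CONCEPTS = {
    "obs_fev1": "fev1",
    "obs_fev1_pct": "fev1_pct_pred",
    "obs_bd_pre": "bronchodilation_pre",
    "obs_bd_post": "bronchodilation_post",
}

#: ethnicity concept -> (EW2011, Scotland2011, harmonised2011, broad)
ETHNICITY_CONCEPTS: dict[str, tuple[str, str, str, str]] = {
    "eth_white_british": ("White British", "White Scottish", "White", "White"),
    "eth_white_other": ("White Other", "White Other British", "White", "White"),
    "eth_indian": ("Asian: Indian", "Asian: Indian", "Asian", "Asian"),
    "eth_pakistani": ("Asian: Pakistani", "Asian: Pakistani", "Asian", "Asian"),
    "eth_african": ("Black: African", "African", "Black", "Black"),
    "eth_caribbean": ("Black: Caribbean", "Caribbean", "Black", "Black"),
    "eth_mixed": ("Mixed", "Mixed or multiple", "Mixed", "Mixed"),
    "eth_other": ("Other ethnic group", "Other ethnic group", "Other", "Other"),
}

#: broad category -> concept keys the generator may pick from.
ETHNICITY_BY_BROAD = {
    "White": ("eth_white_british", "eth_white_other"),
    "Asian": ("eth_indian", "eth_pakistani"),
    "Black": ("eth_african", "eth_caribbean"),
    "Mixed": ("eth_mixed",),
    "Other": ("eth_other",),
}

_CLINICAL_SYSTEMS = (System.MEDCODE, System.SNOMED_CONCEPT, System.READ_V2)


def _tri_system_entries(concept: str, description: str, **kwargs) -> list[CodeEntry]:
    return [
        CodeEntry(clinical_code(concept, system), system, description, **kwargs)
        for system in _CLINICAL_SYSTEMS
    ]


def default_codelists() -> dict[str, Codelist]:
    """All synthetic codelists, keyed by name."""
    lists: dict[str, Codelist] = {}

    for disease in DISEASES:
        entries: list[CodeEntry] = []
        for concept, (d, diagnostic, desc) in _DIAGNOSIS_CONCEPTS.items():
            if d != disease:
                continue
            entries += _tri_system_entries(
                concept, desc, incident=diagnostic, prevalent=True
            )
        lists[disease] = Codelist(disease, Purpose.DIAGNOSIS, tuple(entries))

    subtype_entries: list[CodeEntry] = []
    for concept, subtype in ILD_SUBTYPE_OF.items():
        desc = _DIAGNOSIS_CONCEPTS[concept][2]
        subtype_entries += _tri_system_entries(concept, desc, category=subtype)
    lists["ild_subtype"] = Codelist("ild_subtype", Purpose.ILD_SUBTYPE, tuple(subtype_entries))

    med_entries: list[CodeEntry] = []
    for drug in DRUGS.values():
        for system in (System.DMD, System.BNF, System.READ_V2):
            code = drug_code(drug.key, system)
            if code is not None:
                med_entries.append(
                    CodeEntry(code, system, drug.description, category=drug.category)
                )
    lists["medication"] = Codelist("medication", Purpose.MEDICATION, tuple(med_entries))

    smoking_entries: list[CodeEntry] = []
    for concept, status in _SMOKING_CONCEPTS.items():
        smoking_entries += _tri_system_entries(concept, f"Smoking status: {status}", category=status)
    lists["smoking"] = Codelist("smoking", Purpose.SMOKING, tuple(smoking_entries))

    bmi_entries: list[CodeEntry] = []
    for concept, kind in _BMI_CONCEPTS.items():
        bmi_entries += _tri_system_entries(concept, f"Observation: {kind}", category=kind)
    lists["bmi"] = Codelist("bmi", Purpose.BMI, tuple(bmi_entries))

    spiro_entries: list[CodeEntry] = []
    for concept, kind in _SPIRO_CONCEPTS.items():
        spiro_entries += _tri_system_entries(concept, f"Spirometry: {kind}", category=kind)
    lists["spirometry"] = Codelist("spirometry", Purpose.SPIROMETRY, tuple(spiro_entries))

    eth_entries: list[CodeEntry] = []
    for concept, (ew, scot, harmonised, broad) in ETHNICITY_CONCEPTS.items():
        extra = {
            "eth_ew2011": ew,
            "eth_scot2011": scot,
            "eth_harmonised": harmonised,
            "eth_broad": broad,
        }
        for system in _CLINICAL_SYSTEMS:
            eth_entries.append(
                CodeEntry(
                    clinical_code(concept, system),
                    system,
                    f"Ethnicity: {ew}",
                    category=harmonised,
                    extra=extra,
                )
            )
    lists["ethnicity"] = Codelist("ethnicity", Purpose.ETHNICITY, tuple(eth_entries))

    return lists


def default_mapping() -> CodeMapping:
    """Cross-terminology relation covering the synthetic universe."""
    rows: list[tuple[System, str, System, str]] = []
    concepts = (
        list(_DIAGNOSIS_CONCEPTS)
        + list(_SMOKING_CONCEPTS)
        + list(_BMI_CONCEPTS)
        + list(_SPIRO_CONCEPTS)
        + list(ETHNICITY_CONCEPTS)
    )
    for concept in concepts:
        m = clinical_code(concept, System.MEDCODE)
        sn = clinical_code(concept, System.SNOMED_CONCEPT)
        r = clinical_code(concept, System.READ_V2)
        rows += [
            (System.MEDCODE, m, System.SNOMED_CONCEPT, sn),
            (System.SNOMED_CONCEPT, sn, System.MEDCODE, m),
            (System.MEDCODE, m, System.READ_V2, r),
            (System.READ_V2, r, System.MEDCODE, m),
        ]
    for drug in DRUGS.values():
        dmd = drug_code(drug.key, System.DMD)
        bnf = drug_code(drug.key, System.BNF)
        atc = drug_code(drug.key, System.ATC)
        read = drug_code(drug.key, System.READ_V2)
        rows += [
            (System.DMD, dmd, System.BNF, bnf),
            (System.DMD, dmd, System.ATC, atc),
        ]
        if read is not None:  # ATC→Read rows absent for post-2016 drugs
            rows.append((System.ATC, atc, System.READ_V2, read))
    return CodeMapping(rows)


def write_default_files(directory: str | Path) -> dict[str, Path]:
    """Write every synthetic codelist plus the mapping as CSV files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, codelist in default_codelists().items():
        paths[name] = write_codelist(codelist, directory / f"{name}.csv")
    paths["mapping"] = write_mapping(default_mapping(), directory / "mapping.csv")
    return paths
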