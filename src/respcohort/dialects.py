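"""Source-dialect profiles.

The three supported UK primary-care sources differ systematically in
identifier scope, birth-date granularity, clinical/drug coding systems
and prescription semantics:

* ``cprd_like`` — each GP registration gets its own patient identifier
  (a patient who moves practice appears under several IDs), only year of
  birth is given, clinical events use medcode-style identifiers, drugs
  use product (dm+d-style) codes, prescriptions are GP-issued, and
  events outside a registration window are not usable.
* ``sail_like`` — one identifier per person, week of birth, Read-coded
  events and drugs, GP-issued prescriptions; drugs launched after the
  2016 Read-code deprecation carry no drug code of their own and must be
  found via same-day component prescriptions.
* ``dataloch_like`` — one identifier per person, month+year of birth,
  Read-coded events, BNF-coded *dispensed* prescriptions available only
  from 2009 onwards.

A :class:`DialectProfile` captures those axes so that every downstream
operation can branch on declared dialect properties rather than on
source names.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .codelists import System

__all__ = [
    "BirthGranularity",
    "IdScope",
    "PrescriptionSemantics",
    "DrugCoding",
    "DeprivationScheme",
    "DialectProfile",
    "CPRD_LIKE",
    "SAIL_LIKE",
    "DATALOCH_LIKE",
    "PROFILES",
    "get_profile",
]


class BirthGranularity(str, Enum):
    YEAR = "year"
    WEEK = "week"
    MONTH = "month"
    EXACT = "exact"


class IdScope(str, Enum):
    PER_REGISTRATION = "per_registration"
    PER_PERSON = "per_person"


class PrescriptionSemantics(str, Enum):
    ISSUED = "issued"
    DISPENSED = "dispensed"


class DrugCoding(str, Enum):
    PRODUCT_CODE = "product_code"
    READ = "read"
    BNF = "bnf"


class DeprivationScheme(str, Enum):
    """Area-level deprivation indices; IMD numbers its quintiles in the
    opposite direction to WIMD/SIMD."""

    IMD_ENGLAND_2019 = "imd_england_2019"
    WIMD_2019 = "wimd_2019"
    SIMD_2020V2 = "simd_2020v2"


@dataclass(frozen=True)
class DialectProfile:
    name: str
    birth_granularity: BirthGranularity
    patient_id_scope: IdScope
    prescription_semantics: PrescriptionSemantics
    prescription_start_year: int | None
    drug_coding: DrugCoding
    events_restricted_to_registration: bool
    clinical_system: System
    drug_system: System
    deprivation_scheme: DeprivationScheme
    region: str

    def __post_init__(self) -> None:
        expected = _CANONICAL.get(self.name)
        if expected is not None:
            got = (
                self.birth_granularity,
                self.patient_id_scope,
                self.prescription_semantics,
                self.drug_coding,
                self.events_restricted_to_registration,
            )
            if got != expected:
                raise ValueError(f"profile {self.name!r} violates its dialect invariants")


_CANONICAL = {
    "cprd_like": (
        BirthGranularity.YEAR,
        IdScope.PER_REGISTRATION,
        PrescriptionSemantics.ISSUED,
        DrugCoding.PRODUCT_CODE,
        True,
    ),
    "sail_like": (
        BirthGranularity.WEEK,
        IdScope.PER_PERSON,
        PrescriptionSemantics.ISSUED,
        DrugCoding.READ,
        False,
    ),
    "dataloch_like": (
        BirthGranularity.MONTH,
        IdScope.PER_PERSON,
        PrescriptionSemantics.DISPENSED,
        DrugCoding.BNF,
        False,
    ),
}

CPRD_LIKE = DialectProfile(
    name="cprd_like",
    birth_granularity=BirthGranularity.YEAR,
    patient_id_scope=IdScope.PER_REGISTRATION,
    prescription_semantics=PrescriptionSemantics.ISSUED,
    prescription_start_year=None,
    drug_coding=DrugCoding.PRODUCT_CODE,
    events_restricted_to_registration=True,
    clinical_system=System.MEDCODE,
    drug_system=System.DMD,
    deprivation_scheme=DeprivationScheme.IMD_ENGLAND_2019,
    region="England",
)

SAIL_LIKE = DialectProfile(
    name="sail_like",
    birth_granularity=BirthGranularity.WEEK,
    patient_id_scope=IdScope.PER_PERSON,
    prescription_semantics=PrescriptionSemantics.ISSUED,
    prescription_start_year=None,
    drug_coding=DrugCoding.READ,
    events_restricted_to_registration=False,
    clinical_system=System.READ_V2,
    drug_system=System.READ_V2,
    deprivation_scheme=DeprivationScheme.WIMD_2019,
    region="Wales",
)

DATALOCH_LIKE = DialectProfile(
    name="dataloch_like",
    birth_granularity=BirthGranularity.MONTH,
    patient_id_scope=IdScope.PER_PERSON,
    prescription_semantics=PrescriptionSemantics.DISPENSED,
    prescription_start_year=2009,
    drug_coding=DrugCoding.BNF,
    events_restricted_to_registration=False,
    clinical_system=System.READ_V2,
    drug_system=System.BNF,
    deprivation_scheme=DeprivationScheme.SIMD_2020V2,
    region="Lothian",
)

PROFILES = {p.name: p for p in (CPRD_LIKE, SAIL_LIKE, DATALOCH_LIKE)}


def get_profile(name: str) -> DialectProfile:
    try:
        return PROFILES[name]
    except KeyError:
        raise ValueError(
            f"unknown dialect {name!r}; expected one of {sorted(PROFILES)}"
        ) from None
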