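"""Render a latent population into one source dialect.

Rendering applies exactly the source differences the curation pipeline
must harmonise: birth dates are coarsened to the dialect granularity;
practice movers are split into one patient identifier per registration
in per-registration sources; clinical events are coded in the dialect's
clinical system and prescriptions in its drug system; dispensed-only
sources carry no prescriptions before their coverage start; Read-coded
sources render post-2016 combination inhalers as their same-day
component drugs because no Read code exists for the product.  The
truth manifest maps every emitted patient identifier back to its
latent person.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from ..codelists import Codelist, CodeMapping, System
from ..dialects import DialectProfile, DeprivationScheme, IdScope
from ..demographics import BirthInfo
from ..errors import ConfigurationError
from . import vocab
from .latent import GenerationParams, LatentPerson

__all__ = ["RenderOptions", "EHRBundle", "TruthManifest", "render_dialect"]

_ENGLISH_REGIONS = (
    "North East",
    "North West",
    "Yorkshire and The Humber",
    "East Midlands",
    "West Midlands",
    "East of England",
    "London",
    "South East",
    "South West",
)


@dataclass(frozen=True)
class RenderOptions:
    """Administrative dates of the rendered extract."""

    extraction_date: date = date(2022, 3, 7)
    last_collection_date: date = date(2022, 2, 1)
    ons_coverage_end: date = date(2021, 3, 31)
    deprivation_record_date: date = date(2019, 4, 1)
    #: fraction of BMI observations rendered as a raw weight instead of a
    #: recorded BMI in sources that derive BMI from weight/height
    bmi_as_weight_fraction: float = 0.3
    #: chance of an extra, lower FEV1 entry on the same day
    duplicate_fev1_fraction: float = 0.15


@dataclass
class EHRBundle:
    """Linked tables of one rendered dialect extract."""

    profile_name: str
    patients: pd.DataFrame
    registrations: pd.DataFrame
    clinical_events: pd.DataFrame
    prescriptions: pd.DataFrame
    deaths: pd.DataFrame
    deprivation: pd.DataFrame
    hospital_events: pd.DataFrame
    admin: dict = field(default_factory=dict)

    def table_names(self) -> tuple[str, ...]:
        return (
            "patients",
            "registrations",
            "clinical_events",
            "prescriptions",
            "deaths",
            "deprivation",
            "hospital_events",
        )


@dataclass
class TruthManifest:
    """Latent truth plus the latent-person ↔ rendered-identifier map."""

    persons: list[LatentPerson]
    id_map: dict[str, str]  # patient_id -> person_id

    def __post_init__(self) -> None:
        self._by_person: dict[str, LatentPerson] = {p.person_id: p for p in self.persons}

    def person_for(self, patient_id: str) -> LatentPerson:
        return self._by_person[self.id_map[patient_id]]

    def patient_ids_for(self, person_id: str) -> list[str]:
        return [pid for pid, per in self.id_map.items() if per == person_id]

    def persons_of(self, patient_ids) -> set[str]:
        return {self.id_map[pid] for pid in patient_ids}

    def expected_person_ids(
        self,
        disease: str,
        study_start: date = date(2004, 1, 1),
        latest_event_date: date = date(2019, 12, 31),
        min_event_age_years: float = 0.0,
    ) -> set[str]:
        """Truth-side cohort oracle: persons with the disease, onset on
        or before the latest event date, onset age at or above the
        threshold, recorded sex, and alive into the study era."""
        expected = set()
        for person in self.persons:
            if not person.disease_status.get(disease):
                continue
            onset = person.true_onset_date[disease]
            if onset is None or onset > latest_event_date:
                continue
            if person.sex not in ("male", "female"):
                continue
            if person.true_death_date is not None and person.true_death_date < study_start:
                continue
            onset_age = (onset - person.true_birth_date).days / 365.25
            if onset_age < min_event_age_years:
                continue
            if not person.quality_valid:
                continue
            expected.add(person.person_id)
        return expected


def _check_codelists(codelists: dict[str, Codelist], profile: DialectProfile) -> None:
    for name, codelist in codelists.items():
        system = (
            profile.drug_system if name == "medication" else profile.clinical_system
        )
        if name == "medication" and profile.drug_system is System.READ_V2:
            # Read-coded sources legitimately lack codes for post-2016 drugs
            if codelist.codes(System.READ_V2):
                continue
        if not codelist.codes(system):
            raise ConfigurationError(
                f"codelist {name!r} has no codes in system {system.value!r} "
                f"required by dialect {profile.name!r}"
            )


def render_dialect(
    population: list[LatentPerson],
    profile: DialectProfile,
    codelists: dict[str, Codelist],
    mapping: CodeMapping,
    seed: int,
    params: GenerationParams | None = None,
    options: RenderOptions | None = None,
) -> tuple[EHRBundle, TruthManifest]:
    """Render a latent population into an EHR bundle in one dialect."""
    if not population:
        raise ValueError("population must be non-empty")
    _check_codelists(codelists, profile)
    params = params or GenerationParams()
    options = options or RenderOptions()
    rng = np.random.default_rng(seed)

    clin_sys = profile.clinical_system
    drug_sys = profile.drug_system
    per_registration = profile.patient_id_scope is IdScope.PER_REGISTRATION

    patients_rows: list[tuple] = []
    registration_rows: list[tuple] = []
    event_rows: list[tuple] = []
    prescription_rows: list[tuple] = []
    death_rows: list[tuple] = []
    deprivation_rows: list[tuple] = []
    hospital_rows: list[tuple] = []
    id_map: dict[str, str] = {}

    m_diag = params.missing_rate("diagnosis")
    m_smok = params.missing_rate("smoking")
    m_bmi = params.missing_rate("bmi")
    m_spiro = params.missing_rate("spirometry")
    m_eth = params.missing_rate("ethnicity")
    m_rx = params.missing_rate("prescription")

    for person in population:
        regs = person.registrations
        if per_registration:
            patids = [f"{person.person_id}-r{j}" for j in range(len(regs))]
        else:
            patids = [person.person_id] * len(regs)
            id_map[person.person_id] = person.person_id

        def patid_for(when: date) -> str:
            for j in range(len(regs) - 1, -1, -1):
                if regs[j][0] <= when:
                    return patids[j]
            return patids[0]

        birth_info = BirthInfo.from_exact(person.true_birth_date, profile.birth_granularity)
        for j, (start, end) in enumerate(regs):
            pid = patids[j]
            registration_rows.append((pid, start, end))
            if per_registration or j == 0:
                id_map[pid] = person.person_id
                region = (
                    _ENGLISH_REGIONS[int(rng.integers(0, len(_ENGLISH_REGIONS)))]
                    if profile.name == "cprd_like"
                    else profile.region
                )
                patients_rows.append(
                    (
                        pid,
                        person.sex,
                        birth_info.value,
                        person.quality_valid,  # acceptable / CHI-valid analogue
                        True,  # linkage eligible
                        region,
                    )
                )
                quintile = (
                    person.deprivation_level
                    if profile.deprivation_scheme is DeprivationScheme.IMD_ENGLAND_2019
                    else 6 - person.deprivation_level
                )
                deprivation_rows.append(
                    (
                        pid,
                        profile.deprivation_scheme.value,
                        quintile,
                        options.deprivation_record_date,
                    )
                )

        # ------------------------------------------------- clinical events
        for when, _disease, concept in person.diagnosis_events:
            if m_diag and rng.random() < m_diag:
                continue
            event_rows.append(
                (patid_for(when), when, vocab.clinical_code(concept, clin_sys), clin_sys.value, np.nan)
            )
        for when, status in person.smoking_observations:
            if m_smok and rng.random() < m_smok:
                continue
            concept = f"smok_{status}"
            event_rows.append(
                (patid_for(when), when, vocab.clinical_code(concept, clin_sys), clin_sys.value, np.nan)
            )
        height_emitted = False
        if person.height_observation is not None:
            h_when, h_val = person.height_observation
            if not (m_bmi and rng.random() < m_bmi):
                event_rows.append(
                    (
                        patid_for(h_when),
                        h_when,
                        vocab.clinical_code("obs_height", clin_sys),
                        clin_sys.value,
                        h_val,
                    )
                )
                height_emitted = True
        for when, bmi in person.bmi_observations:
            if m_bmi and rng.random() < m_bmi:
                continue
            as_weight = (
                profile.name != "dataloch_like"
                and height_emitted
                and rng.random() < options.bmi_as_weight_fraction
            )
            if as_weight:
                weight = bmi * person.height * person.height
                event_rows.append(
                    (
                        patid_for(when),
                        when,
                        vocab.clinical_code("obs_weight", clin_sys),
                        clin_sys.value,
                        weight,
                    )
                )
            else:
                event_rows.append(
                    (
                        patid_for(when),
                        when,
                        vocab.clinical_code("obs_bmi", clin_sys),
                        clin_sys.value,
                        bmi,
                    )
                )
        for when, fev1, gp_pct, bd in person.spirometry_observations:
            if m_spiro and rng.random() < m_spiro:
                continue
            pid = patid_for(when)
            event_rows.append(
                (pid, when, vocab.clinical_code("obs_fev1", clin_sys), clin_sys.value, fev1)
            )
            if rng.random() < options.duplicate_fev1_fraction:
                event_rows.append(
                    (
                        pid,
                        when,
                        vocab.clinical_code("obs_fev1", clin_sys),
                        clin_sys.value,
                        round(fev1 * 0.9, 3),
                    )
                )
            if gp_pct is not None:
                event_rows.append(
                    (
                        pid,
                        when,
                        vocab.clinical_code("obs_fev1_pct", clin_sys),
                        clin_sys.value,
                        gp_pct,
                    )
                )
            if bd is not None:
                event_rows.append(
                    (
                        pid,
                        when,
                        vocab.clinical_code(f"obs_bd_{bd}", clin_sys),
                        clin_sys.value,
                        np.nan,
                    )
                )
        if person.ethnicity_gp_date is not None and not (m_eth and rng.random() < m_eth):
            when = person.ethnicity_gp_date
            event_rows.append(
                (
                    patid_for(when),
                    when,
                    vocab.clinical_code(person.ethnicity_concept, clin_sys),
                    clin_sys.value,
                    np.nan,
                )
            )
        if person.ethnicity_hospital_date is not None:
            when = person.ethnicity_hospital_date
            hospital_rows.append(
                (
                    patid_for(when),
                    when,
                    vocab.clinical_code(person.ethnicity_concept, clin_sys),
                    clin_sys.value,
                )
            )

        # ---------------------------------------------------- prescriptions
        for when, drug_key in person.prescriptions:
            if m_rx and rng.random() < m_rx:
                continue
            if (
                profile.prescription_start_year is not None
                and when.year < profile.prescription_start_year
            ):
                continue  # dispensed records unavailable before coverage start
            pid = patid_for(when)
            code = vocab.drug_code(drug_key, drug_sys)
            if code is not None:
                prescription_rows.append((pid, when, code, drug_sys.value))
            else:
                # no code for this product in Read: prescribe components same-day
                for component in vocab.DRUGS[drug_key].components:
                    comp_code = vocab.drug_code(component, drug_sys)
                    if comp_code is not None:
                        prescription_rows.append((pid, when, comp_code, drug_sys.value))

        # ----------------------------------------------------------- deaths
        if person.true_death_date is not None:
            death = person.true_death_date
            pid = patid_for(death)
            if profile.name == "dataloch_like":
                death_rows.append((pid, None, None, death))
            else:
                recorded: date | None = death
                registration_date = None
                if (
                    params.ons_death_date_missing_rate
                    and rng.random() < params.ons_death_date_missing_rate
                ):
                    recorded = None
                    registration_date = death + timedelta(days=5)
                internal = death if profile.name == "cprd_like" else None
                death_rows.append((pid, recorded, registration_date, internal))

    patients = pd.DataFrame(
        patients_rows,
        columns=["patient_id", "sex", "birth", "acceptable", "linkage_eligible", "region"],
    )
    registrations = pd.DataFrame(registration_rows, columns=["patient_id", "start", "end"])
    clinical_events = pd.DataFrame(
        event_rows, columns=["patient_id", "date", "code", "system", "value"]
    )
    prescriptions = pd.DataFrame(
        prescription_rows, columns=["patient_id", "date", "code", "system"]
    )
    deaths = pd.DataFrame(
        death_rows, columns=["patient_id", "death_date", "registration_date", "internal_date"]
    )
    deprivation = pd.DataFrame(
        deprivation_rows, columns=["patient_id", "scheme", "quintile", "record_date"]
    )
    hospital_events = pd.DataFrame(
        hospital_rows, columns=["patient_id", "date", "code", "system"]
    )
    for frame in (registrations, clinical_events, prescriptions, hospital_events):
        if "date" in frame.columns:
            frame["date"] = pd.to_datetime(frame["date"])
    registrations["start"] = pd.to_datetime(registrations["start"])
    registrations["end"] = pd.to_datetime(registrations["end"])
    for column in ("death_date", "registration_date", "internal_date"):
        deaths[column] = pd.to_datetime(deaths[column])
    deprivation["record_date"] = pd.to_datetime(deprivation["record_date"])

    bundle = EHRBundle(
        profile_name=profile.name,
        patients=patients,
        registrations=registrations,
        clinical_events=clinical_events,
        prescriptions=prescriptions,
        deaths=deaths,
        deprivation=deprivation,
        hospital_events=hospital_events,
        admin={
            "extraction_date": options.extraction_date,
            "last_collection_date": options.last_collection_date,
            "ons_coverage_end": options.ons_coverage_end,
            "prescription_semantics": profile.prescription_semantics.value,
        },
    )
    manifest = TruthManifest(persons=list(population), id_map=id_map)
    return bundle, manifest
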