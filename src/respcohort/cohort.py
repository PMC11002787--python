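"""Harmonised cohort construction.

A disease cohort includes patients of recorded sex with at least one
valid disease event on or before the study's latest event date who were
alive and registered at any time from the study start.  An event is
valid when it lies within the patient's lifetime (against the imputed
birth date — what the source could observe), on or before the latest
event date, and at or above the disease's minimum age (35 for COPD, 40
for ILD).  Exclusions are applied in a fixed, documented order — sex,
valid event, alive/registered in the study era, dialect-specific
quality flags — and tallied under the first criterion that removes a
patient, so the attrition flowchart conserves the input count.

Two diagnosis dates are derived per member.  The *earliest mention* is
the first valid disease code of any kind.  The *date of incidence* is
the first incident-classified code, blanked when the earliest mention
falls within the first year of registration: chronic disease recorded
shortly after joining a practice is usually prevalent disease entering
a fresh record, not new disease.  In per-registration sources each
registration (identifier) is assessed independently, which is exactly
why that masking rule matters there.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Iterable, NamedTuple

import pandas as pd

from .codelists import Codelist, EventClass, Purpose
from .dateutils import add_calendar_years, as_date
from .demographics import (
    DeprivationRecord,
    derive_ethnicity,
    harmonise_deprivation,
    impute_birth_date,
    BirthInfo,
    resolve_death_date,
)
from .dialects import DialectProfile, IdScope
from .errors import IntegrityError, ValidationError
from .synth.render import EHRBundle

__all__ = [
    "CohortSpec",
    "FollowUp",
    "CohortResult",
    "EXCLUSION_ORDER",
    "ILD_SUBTYPE_FLAGS",
    "restrict_events_to_registration",
    "compute_followup",
    "derive_diagnosis_dates",
    "apply_cohort_criteria",
    "classify_ild_subtypes",
]

_MIN_EVENT_AGE = {"asthma": 0.0, "copd": 35.0, "ild": 40.0}

EXCLUSION_ORDER = (
    "sex_not_male_female",
    "no_valid_disease_event",
    "not_alive_and_registered_from_2004",
    "failed_dialect_quality_criteria",
)

ILD_SUBTYPE_FLAGS = (
    "ipf_broad",
    "ipf_narrow",
    "exposure_related",
    "autoimmune_related",
    "treatment_related",
    "other",
)


@dataclass(frozen=True)
class CohortSpec:
    """Inclusion parameters for one disease cohort."""

    disease: str
    min_event_age_years: float = 0.0
    study_start: date = date(2004, 1, 1)
    latest_event_date: date = date(2019, 12, 31)

    def __post_init__(self) -> None:
        if self.disease not in _MIN_EVENT_AGE:
            raise ValidationError(f"unknown disease {self.disease!r}")
        if self.min_event_age_years < 0:
            raise ValidationError("min_event_age_years must be >= 0")
        if self.study_start >= self.latest_event_date:
            raise ValidationError("study_start must precede latest_event_date")

    @classmethod
    def for_disease(cls, disease: str, **overrides) -> "CohortSpec":
        """Standard thresholds: COPD 35, ILD 40, asthma none."""
        overrides.setdefault("min_event_age_years", _MIN_EVENT_AGE[disease])
        return cls(disease=disease, **overrides)


class FollowUp(NamedTuple):
    start: date
    end: date
    valid: bool


@dataclass
class CohortResult:
    members: pd.DataFrame
    tally: dict[str, int]
    reasons: pd.Series  # patient_id -> first failing criterion
    n_input: int
    spec: CohortSpec
    profile_name: str

    @property
    def patient_ids(self) -> set[str]:
        return set(self.members["patient_id"])

    def conserved(self) -> bool:
        return len(self.members) + sum(self.tally.values()) == self.n_input


def restrict_events_to_registration(
    events: pd.DataFrame, registrations: pd.DataFrame, profile: DialectProfile
) -> pd.DataFrame:
    """Drop events outside the patient's registration window in
    per-registration sources; pass through unchanged elsewhere."""
    unknown = set(events["patient_id"]) - set(registrations["patient_id"])
    if unknown:
        raise IntegrityError(
            f"events reference unknown patient_id(s): {sorted(unknown)[:5]}"
        )
    if not profile.events_restricted_to_registration or len(events) == 0:
        return events
    merged = events.reset_index(names="_event_idx").merge(
        registrations[["patient_id", "start", "end"]], on="patient_id", how="left"
    )
    dates = pd.to_datetime(merged["date"])
    keep = (dates >= merged["start"]) & (merged["end"].isna() | (dates <= merged["end"]))
    kept = merged[keep].drop_duplicates("_event_idx")  # event in any window survives once
    return kept[events.columns.tolist()].reset_index(drop=True)


def compute_followup(
    patient_id: str,
    registrations: pd.DataFrame,
    death: date | None,
    profile: DialectProfile,
    admin_dates: dict,
) -> FollowUp:
    """Follow-up window for one patient.

    Per-registration sources: registration start to the earliest of
    death, last practice collection date and registration end (transfer
    out).  Per-person sources: minimum registration start to the
    earliest of death, maximum registration end and extraction date.
    """
    regs = registrations[registrations["patient_id"] == patient_id]
    if len(regs) == 0:
        raise ValidationError(f"patient {patient_id!r} has no registrations")
    starts = pd.to_datetime(regs["start"])
    ends = pd.to_datetime(regs["end"])
    if profile.patient_id_scope is IdScope.PER_REGISTRATION:
        start = as_date(starts.min())
        candidates = [death, admin_dates.get("last_collection_date")]
        if ends.notna().any():
            candidates.append(as_date(ends.dropna().min()))
    else:
        start = as_date(starts.min())
        candidates = [death, admin_dates.get("extraction_date")]
        if not ends.isna().any():  # an open registration has no end yet
            candidates.append(as_date(ends.max()))
    candidates = [c for c in candidates if c is not None]
    if not candidates:
        raise ValidationError(f"patient {patient_id!r}: no follow-up end candidate")
    end = min(candidates)
    return FollowUp(start=start, end=end, valid=end >= start)


def derive_diagnosis_dates(
    classified_events: Iterable[tuple[date, EventClass | str]],
    followup_start: date,
) -> tuple[date, date | None]:
    """Earliest mention and date of incidence from classified events.

    Earliest mention is the minimum event date over all classifications;
    date of incidence is the minimum over incident-classified events,
    blanked when the earliest mention falls within the first year of
    registration (the half-open interval [start, start + 1 calendar
    year)).
    """
    events = [(as_date(d), EventClass(c)) for d, c in classified_events]
    if not events:
        raise ValidationError("cannot derive diagnosis dates from no events")
    earliest_mention = min(d for d, _ in events)
    incident_dates = [d for d, c in events if c is EventClass.INCIDENT_AND_PREVALENT]
    date_of_incidence = min(incident_dates) if incident_dates else None
    if earliest_mention < add_calendar_years(as_date(followup_start), 1):
        date_of_incidence = None
    return earliest_mention, date_of_incidence


def classify_ild_subtypes(
    events: pd.DataFrame, subtype_codelists: Codelist | Iterable[Codelist]
) -> dict[str, frozenset[str]]:
    """Independent subtype flags per patient from coded events.

    Flags: ipf_broad, ipf_narrow (narrow implies broad), exposure_related,
    autoimmune_related, treatment_related, other.  No single final label
    is assigned; a patient may carry any combination.
    """
    if isinstance(subtype_codelists, Codelist):
        subtype_codelists = [subtype_codelists]
    index: dict[tuple, str] = {}
    for codelist in subtype_codelists:
        if codelist.purpose is not Purpose.ILD_SUBTYPE:
            raise ValidationError(f"codelist {codelist.name!r} is not an ILD subtype list")
        for entry in codelist:
            if entry.category:
                index[(entry.code, entry.system)] = entry.category
    flags: dict[str, set[str]] = {}
    for row in events.itertuples(index=False):
        subtype = index.get((str(row.code), str(row.system)))
        if subtype is None:
            continue
        patient_flags = flags.setdefault(row.patient_id, set())
        patient_flags.add(subtype)
        if subtype == "ipf_narrow":
            patient_flags.add("ipf_broad")
    return {pid: frozenset(s) for pid, s in flags.items()}


# ------------------------------------------------------------------ engine


def _impute_birth_series(patients: pd.DataFrame, profile: DialectProfile) -> pd.Series:
    values = patients["birth"].astype(str)
    cache: dict[str, pd.Timestamp] = {}
    out = []
    for value in values:
        ts = cache.get(value)
        if ts is None:
            ts = pd.Timestamp(
                impute_birth_date(BirthInfo(profile.birth_granularity, value), profile)
            )
            cache[value] = ts
        out.append(ts)
    return pd.Series(out, index=patients["patient_id"].values, name="birth_imputed")


def _resolve_deaths(deaths: pd.DataFrame, profile: DialectProfile, admin: dict) -> pd.Series:
    coverage_end = admin.get("ons_coverage_end", date(2021, 3, 31))
    resolved = {}
    for row in deaths.itertuples(index=False):
        primary = None
        if not (pd.isna(row.death_date) and pd.isna(row.registration_date)):
            primary = {
                "death_date": None if pd.isna(row.death_date) else as_date(row.death_date),
                "registration_date": None
                if pd.isna(row.registration_date)
                else as_date(row.registration_date),
            }
        internal = None if pd.isna(row.internal_date) else as_date(row.internal_date)
        res = resolve_death_date(primary, internal, coverage_end, profile)
        if res.date is not None:
            resolved[row.patient_id] = pd.Timestamp(res.date)
    return pd.Series(resolved, name="death_date", dtype="datetime64[ns]")


def _followup_frame(
    registrations: pd.DataFrame,
    death: pd.Series,
    profile: DialectProfile,
    admin: dict,
) -> pd.DataFrame:
    grouped = registrations.groupby("patient_id")
    start = grouped["start"].min()
    has_open = grouped["end"].apply(lambda s: s.isna().any())
    if profile.patient_id_scope is IdScope.PER_REGISTRATION:
        reg_end = grouped["end"].min()
        extra = admin.get("last_collection_date")
    else:
        reg_end = grouped["end"].max()
        extra = admin.get("extraction_date")
    reg_end = reg_end.where(~has_open, pd.NaT)
    frame = pd.DataFrame({"followup_start": start, "reg_end": reg_end})
    frame = frame.join(death.rename("death"))
    candidates = [frame["reg_end"], frame["death"]]
    if extra is not None:
        candidates.append(pd.Series(pd.Timestamp(extra), index=frame.index))
    frame["followup_end"] = pd.concat(candidates, axis=1).min(axis=1, skipna=True)
    frame["followup_valid"] = frame["followup_end"].notna() & (
        frame["followup_end"] >= frame["followup_start"]
    )
    return frame


def _completed_years(events: pd.Series, births: pd.Series) -> pd.Series:
    before_birthday = (events.dt.month < births.dt.month) | (
        (events.dt.month == births.dt.month) & (events.dt.day < births.dt.day)
    )
    return events.dt.year - births.dt.year - before_birthday.astype(int)


def _add_one_year(series: pd.Series) -> pd.Series:
    day = series.dt.day.where(~((series.dt.month == 2) & (series.dt.day == 29)), 28)
    return pd.to_datetime(
        {"year": series.dt.year + 1, "month": series.dt.month, "day": day}
    )


_ENGLISH_REGIONS = {
    "North East",
    "North West",
    "Yorkshire and The Humber",
    "East Midlands",
    "West Midlands",
    "East of England",
    "London",
    "South East",
    "South West",
}


def apply_cohort_criteria(
    bundle: EHRBundle,
    spec: CohortSpec,
    codelist: Codelist,
    profile: DialectProfile,
    ethnicity_codelist: Codelist | None = None,
    subtype_codelists: Codelist | Iterable[Codelist] | None = None,
) -> CohortResult:
    """Apply the harmonised inclusion/exclusion criteria to a bundle.

    Returns the cohort members with follow-up windows, diagnosis dates
    and demographics, plus an exclusion tally with one count per named
    criterion in application order (a patient is tallied under the
    first criterion that removes them), so that included + excluded
    equals the input patient count.
    """
    if codelist.purpose is not Purpose.DIAGNOSIS:
        raise ValidationError("cohort construction needs a diagnosis codelist")
    patients = bundle.patients
    n_input = len(patients)
    admin = dict(bundle.admin)

    birth = _impute_birth_series(patients, profile)
    death = _resolve_deaths(bundle.deaths, profile, admin)
    followup = _followup_frame(bundle.registrations, death, profile, admin)

    events = restrict_events_to_registration(
        bundle.clinical_events, bundle.registrations, profile
    )
    entry_frame = pd.DataFrame(
        [
            {
                "code": e.code,
                "system": e.system.value,
                "incident": e.incident,
            }
            for e in codelist
        ]
    )
    disease = events.merge(entry_frame, on=["code", "system"], how="inner")
    if len(disease):
        disease = disease.copy()
        disease["date"] = pd.to_datetime(disease["date"])
        disease["birth"] = disease["patient_id"].map(birth)
        disease["death"] = disease["patient_id"].map(death)
        age = _completed_years(disease["date"], disease["birth"])
        valid = (
            (disease["date"] >= disease["birth"])
            & (disease["death"].isna() | (disease["date"] <= disease["death"]))
            & (disease["date"] <= pd.Timestamp(spec.latest_event_date))
            & (age >= spec.min_event_age_years)
        )
        disease = disease[valid]

    # ------------------------------------------------- exclusion cascade
    index = patients.set_index("patient_id")
    sex_ok = index["sex"].isin(["male", "female"])
    has_event = pd.Series(False, index=index.index)
    if len(disease):
        has_event.loc[has_event.index.isin(set(disease["patient_id"]))] = True
    fu = followup.reindex(index.index)
    era_ok = fu["followup_valid"].fillna(False) & (
        fu["followup_end"] >= pd.Timestamp(spec.study_start)
    )
    if profile.name == "cprd_like":
        dialect_ok = (
            index["acceptable"].astype(bool)
            & index["linkage_eligible"].astype(bool)
            & index["region"].isin(_ENGLISH_REGIONS)
        )
    elif profile.name == "dataloch_like":
        dialect_ok = index["acceptable"].astype(bool)
    else:
        dialect_ok = pd.Series(True, index=index.index)

    reasons = pd.Series("included", index=index.index, name="reason")
    for name, ok in [
        ("sex_not_male_female", sex_ok),
        ("no_valid_disease_event", has_event),
        ("not_alive_and_registered_from_2004", era_ok),
        ("failed_dialect_quality_criteria", dialect_ok),
    ]:
        reasons[(reasons == "included") & ~ok] = name
    tally = {name: int((reasons == name).sum()) for name in EXCLUSION_ORDER}
    included = reasons[reasons == "included"].index

    # --------------------------------------------------- diagnosis dates
    members = pd.DataFrame({"patient_id": included})
    if len(members):
        inc_events = disease[disease["patient_id"].isin(set(included))]
        earliest = inc_events.groupby("patient_id")["date"].min()
        incident_only = inc_events[inc_events["incident"]]
        doi = incident_only.groupby("patient_id")["date"].min()
        members["earliest_mention"] = members["patient_id"].map(earliest)
        members["date_of_incidence"] = members["patient_id"].map(doi)
        members["followup_start"] = members["patient_id"].map(fu["followup_start"])
        members["followup_end"] = members["patient_id"].map(fu["followup_end"])
        first_year_end = _add_one_year(members["followup_start"])
        masked = members["earliest_mention"] < first_year_end
        members.loc[masked, "date_of_incidence"] = pd.NaT
        members["birth_date_imputed"] = members["patient_id"].map(birth)
        members["death_date"] = members["patient_id"].map(death)
        members["sex"] = members["patient_id"].map(index["sex"])
        members["region"] = members["patient_id"].map(index["region"])
        members["age_at_earliest_mention"] = _completed_years(
            members["earliest_mention"], members["birth_date_imputed"]
        )

        # deprivation: latest record per patient, reported as a label
        depriv = bundle.deprivation
        if len(depriv):
            latest = (
                depriv.sort_values("record_date").drop_duplicates("patient_id", keep="last")
            ).set_index("patient_id")
            latest = latest.loc[latest.index.intersection(members["patient_id"])]
            labels = {
                pid: harmonise_deprivation(
                    DeprivationRecord(row["scheme"], int(row["quintile"]))
                )
                for pid, row in latest.iterrows()
            }
            members["deprivation_label"] = members["patient_id"].map(labels)
        else:
            members["deprivation_label"] = None

        # ethnicity: GP codes first, hospital top-up
        if ethnicity_codelist is not None:
            eth_codes = {
                (e.code, e.system.value) for e in ethnicity_codelist
            }
            def _eth_mask(frame: pd.DataFrame) -> pd.DataFrame:
                if len(frame) == 0:
                    return frame
                key = list(zip(frame["code"], frame["system"]))
                return frame[[k in eth_codes for k in key]]

            gp_eth = _eth_mask(bundle.clinical_events)
            hosp_eth = _eth_mask(bundle.hospital_events)
            gp_groups = dict(tuple(gp_eth.groupby("patient_id"))) if len(gp_eth) else {}
            hosp_groups = (
                dict(tuple(hosp_eth.groupby("patient_id"))) if len(hosp_eth) else {}
            )
            broad, harmonised = [], []
            for pid in members["patient_id"]:
                result = derive_ethnicity(
                    gp_groups.get(pid), hosp_groups.get(pid), ethnicity_codelist
                )
                broad.append(result.broad_or_missing)
                harmonised.append(result.harmonised2011)
            members["ethnicity_broad"] = broad
            members["ethnicity_harmonised"] = harmonised
        else:
            members["ethnicity_broad"] = "Missing"
            members["ethnicity_harmonised"] = None

        if spec.disease == "ild" and subtype_codelists is not None:
            subtype_events = events[events["patient_id"].isin(set(included))]
            flags = classify_ild_subtypes(subtype_events, subtype_codelists)
            for flag in ILD_SUBTYPE_FLAGS:
                members[f"ild_{flag}"] = [
                    flag in flags.get(pid, frozenset()) for pid in members["patient_id"]
                ]
    else:
        members = pd.DataFrame(
            columns=[
                "patient_id",
                "earliest_mention",
                "date_of_incidence",
                "followup_start",
                "followup_end",
                "birth_date_imputed",
                "death_date",
                "sex",
                "region",
                "age_at_earliest_mention",
                "deprivation_label",
                "ethnicity_broad",
                "ethnicity_harmonised",
            ]
        )

    return CohortResult(
        members=members.reset_index(drop=True),
        tally=tally,
        reasons=reasons,
        n_input=n_input,
        spec=spec,
        profile_name=profile.name,
    )
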