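"""Harmonised cohort description.

Characterises a cohort at an index date: socio-demographics as
frequency tables (with explicit Missing rows so every table conserves
the cohort count), clinical measures as the most recent value in a
five-year lookback window, medication usage as the number of members
with any prescription per drug category in the index year, and the
age-at-first-mention distribution by sex.  Deprivation is reported as
descriptive labels only, never raw quintiles, because the underlying
schemes number their quintiles in opposite directions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .codelists import Codelist
from .cohort import CohortResult, ILD_SUBTYPE_FLAGS
from .dateutils import as_date
from .dialects import DialectProfile
from .measures import (
    PlausibleRanges,
    build_bmi_record,
    build_smoking_record,
    build_spirometry_record,
    latest_in_window,
)
from .medications import annual_category_usage
from .synth.render import EHRBundle, TruthManifest

__all__ = [
    "CohortDescription",
    "ConcordanceReport",
    "WHO_BMI_BANDS",
    "build_patient_records",
    "describe_cohort",
    "age_at_first_mention_distribution",
    "compare_dialect_cohorts",
]

#: WHO adult BMI bands (kg/m^2), upper bound exclusive.
WHO_BMI_BANDS = (
    ("<18.5", 0.0, 18.5),
    ("18.5-24.9", 18.5, 25.0),
    ("25-29.9", 25.0, 30.0),
    (">=30", 30.0, float("inf")),
)


def build_patient_records(
    bundle: EHRBundle,
    members: pd.DataFrame,
    codelists: Mapping[str, Codelist],
    profile: DialectProfile,
    ranges: PlausibleRanges | None = None,
) -> dict[str, dict[str, pd.DataFrame]]:
    """Cleaned longitudinal smoking/BMI/spirometry records per member.

    ``members`` must carry patient_id, sex and birth_date_imputed (as
    produced by the cohort builder).  Returns
    {patient_id: {"smoking": ..., "bmi": ..., "spirometry": ..., "drops": ...}}.
    """
    ranges = ranges or PlausibleRanges()
    wanted = set(members["patient_id"])
    events = bundle.clinical_events
    events = events[events["patient_id"].isin(wanted)]
    groups = dict(tuple(events.groupby("patient_id"))) if len(events) else {}
    empty = events.iloc[0:0]

    smoking_cl, bmi_cl, spiro_cl = (
        codelists["smoking"],
        codelists["bmi"],
        codelists["spirometry"],
    )
    bmi_category = {
        (e.code, e.system.value): e.category for e in bmi_cl if e.category
    }
    info = members.set_index("patient_id")
    records: dict[str, dict[str, pd.DataFrame]] = {}
    for pid in members["patient_id"]:
        patient_events = groups.get(pid, empty)
        kinds = [
            bmi_category.get((c, s)) for c, s in zip(patient_events["code"], patient_events["system"])
        ]
        kinds = pd.Series(kinds, index=patient_events.index)
        bmi_events = patient_events[kinds == "bmi"][["date", "value"]]
        weight_events = patient_events[kinds == "weight"][["date", "value"]]
        height_events = patient_events[kinds == "height"][["date", "value"]]
        birth = as_date(info.loc[pid, "birth_date_imputed"])
        smoking = build_smoking_record(patient_events, smoking_cl)
        bmi_rec = build_bmi_record(
            bmi_events, weight_events, height_events, birth, profile, ranges
        )
        spiro_rec = build_spirometry_record(
            patient_events,
            sex=str(info.loc[pid, "sex"]),
            birth_date=birth,
            codelist=spiro_cl,
            height_record=height_events.rename(columns={"value": "value"}),
            ranges=ranges,
        )
        non_empty = [d for d in (bmi_rec.dropped, spiro_rec.dropped) if len(d)]
        if non_empty:
            drops = pd.concat(non_empty, ignore_index=True)
        else:
            drops = bmi_rec.dropped
        records[pid] = {
            "smoking": smoking,
            "bmi": bmi_rec.observations,
            "spirometry": spiro_rec.observations,
            "drops": drops,
        }
    return records


@dataclass
class CohortDescription:
    """Frequency tables and summaries describing a cohort at an index date."""

    disease: str
    index_date: date
    lookback_window: tuple[date, date]
    n: int
    tables: dict[str, pd.DataFrame]
    stats: dict[str, float] = field(default_factory=dict)
    medication_usage: dict[str, int] = field(default_factory=dict)
    ild_subtype_counts: dict[str, int] = field(default_factory=dict)

    def conservation_ok(self) -> bool:
        return all(int(t["count"].sum()) == self.n for t in self.tables.values())

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "disease": self.disease,
            "index_date": self.index_date.isoformat(),
            "lookback_window": [d.isoformat() for d in self.lookback_window],
            "n": self.n,
            "tables": {k: t.to_dict(orient="records") for k, t in self.tables.items()},
            "stats": self.stats,
            "medication_usage": self.medication_usage,
            "ild_subtype_counts": self.ild_subtype_counts,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


def _frequency_table(values: Iterable, n: int, order: Iterable | None = None) -> pd.DataFrame:
    series = pd.Series(list(values), dtype=object)
    series = series.where(series.notna(), "Missing")
    counts = series.value_counts()
    if order is not None:
        counts = counts.reindex(
            [v for v in order if v in counts.index]
            + [v for v in counts.index if v not in set(order)]
        ).dropna()
    frame = counts.rename_axis("value").reset_index(name="count")
    frame["count"] = frame["count"].astype(int)
    frame["percent"] = np.where(n > 0, frame["count"] / max(n, 1) * 100.0, 0.0).round(2)
    return frame


def describe_cohort(
    cohort: CohortResult,
    records: Mapping[str, Mapping[str, pd.DataFrame]],
    medication_flags: pd.DataFrame,
    index_date: date = date(2019, 12, 31),
    lookback_years: int = 5,
    profile: DialectProfile | None = None,
    registrations: pd.DataFrame | None = None,
) -> CohortDescription:
    """Describe a cohort at an index date with a measurement lookback.

    Members must be alive with follow-up covering the index date.
    Clinical measures take each member's most recent observation inside
    the lookback window (both bounds inclusive); medication usage
    counts members with any prescription per category in the index
    year.  An empty cohort produces zero-count tables, not an error.
    """
    index_ts = pd.Timestamp(index_date)
    window_start = date(index_date.year - lookback_years + 1, 1, 1)
    members = cohort.members
    if len(members):
        alive = members["death_date"].isna() | (members["death_date"] >= index_ts)
        covered = (members["followup_start"] <= index_ts) & (
            members["followup_end"] >= index_ts
        )
        members = members[alive & covered]
    n = len(members)

    tables: dict[str, pd.DataFrame] = {}
    stats: dict[str, float] = {}
    tables["sex"] = _frequency_table(members.get("sex", []), n, order=["male", "female"])
    tables["ethnicity_broad"] = _frequency_table(
        members.get("ethnicity_broad", []),
        n,
        order=["White", "Black", "Asian", "Mixed", "Other", "Missing"],
    )
    tables["deprivation"] = _frequency_table(
        members.get("deprivation_label", []),
        n,
        order=["most deprived", "2", "3", "4", "least deprived", "Missing"],
    )

    smoking_values, bmi_values, gold_values = [], [], []
    for pid in members["patient_id"] if n else []:
        record = records.get(pid, {})
        latest_smoking = latest_in_window(
            record.get("smoking"), index_date, window_start
        )
        smoking_values.append(None if latest_smoking is None else latest_smoking["status"])
        latest_bmi = latest_in_window(record.get("bmi"), index_date, window_start)
        bmi_values.append(None if latest_bmi is None else float(latest_bmi["bmi"]))
        spiro = record.get("spirometry")
        latest_spiro = latest_in_window(spiro, index_date, window_start)
        if latest_spiro is None or pd.isna(latest_spiro["gold_stage"]):
            gold_values.append(None)
        else:
            gold_values.append(int(latest_spiro["gold_stage"]))

    tables["smoking"] = _frequency_table(
        smoking_values, n, order=["never", "ex", "current", "Missing"]
    )
    bmi_bands = []
    for value in bmi_values:
        if value is None:
            bmi_bands.append(None)
        else:
            for label, lo, hi in WHO_BMI_BANDS:
                if lo <= value < hi:
                    bmi_bands.append(label)
                    break
    tables["bmi_category"] = _frequency_table(
        bmi_bands, n, order=[b[0] for b in WHO_BMI_BANDS] + ["Missing"]
    )
    present_bmi = [v for v in bmi_values if v is not None]
    if present_bmi:
        stats["bmi_median"] = float(np.median(present_bmi))
        stats["bmi_q1"] = float(np.percentile(present_bmi, 25))
        stats["bmi_q3"] = float(np.percentile(present_bmi, 75))
    if cohort.spec.disease == "copd":
        tables["gold_stage"] = _frequency_table(
            gold_values, n, order=[1, 2, 3, 4, "Missing"]
        )

    ild_counts: dict[str, int] = {}
    if cohort.spec.disease == "ild":
        for flag in ILD_SUBTYPE_FLAGS:
            column = f"ild_{flag}"
            if column in members.columns:
                ild_counts[flag] = int(members[column].sum())

    usage = annual_category_usage(
        medication_flags,
        members,
        index_date.year,
        profile=profile,
        registrations=registrations,
        copd_cohort=cohort.spec.disease == "copd",
    )
    return CohortDescription(
        disease=cohort.spec.disease,
        index_date=index_date,
        lookback_window=(window_start, index_date),
        n=n,
        tables=tables,
        stats=stats,
        medication_usage=usage,
        ild_subtype_counts=ild_counts,
    )


def age_at_first_mention_distribution(
    cohort: CohortResult | pd.DataFrame,
    age_cap: int = 93,
    min_age: int | None = None,
) -> pd.DataFrame:
    """Proportion of the cohort by integer age at earliest mention,
    stratified by sex.

    Ages above ``age_cap`` are pooled into the cap (small-number
    protection); an optional display floor pools young ages upward.
    Proportions are computed within each sex stratum and sum to 100 per
    stratum.
    """
    members = cohort.members if isinstance(cohort, CohortResult) else cohort
    if len(members) == 0:
        return pd.DataFrame(columns=["age", "sex", "count", "proportion"])
    ages = members["age_at_earliest_mention"].clip(upper=age_cap)
    if min_age is not None:
        ages = ages.clip(lower=min_age)
    frame = pd.DataFrame({"age": ages.astype(int), "sex": members["sex"]})
    counts = frame.groupby(["sex", "age"]).size().rename("count").reset_index()
    totals = counts.groupby("sex")["count"].transform("sum")
    counts["proportion"] = counts["count"] / totals * 100.0
    return counts[["age", "sex", "count", "proportion"]]


@dataclass
class ConcordanceReport:
    """Person-level cross-dialect cohort agreement with attributions."""

    membership: pd.DataFrame  # person_id + included_<dialect> columns
    discrepancies: pd.DataFrame  # person_id, dialect, attributed_reasons
    unattributed: int

    @property
    def n_discrepant(self) -> int:
        return len(self.discrepancies)


def compare_dialect_cohorts(
    results: Mapping[str, CohortResult],
    manifests: Mapping[str, TruthManifest],
) -> ConcordanceReport:
    """Compare cohort membership across dialect renders of one latent
    population, attributing every discrepancy to the exclusion tally of
    the dialect that dropped the person."""
    included_persons = {
        dialect: manifests[dialect].persons_of(result.patient_ids)
        for dialect, result in results.items()
    }
    union: set[str] = set().union(*included_persons.values()) if included_persons else set()
    membership = pd.DataFrame({"person_id": sorted(union)})
    for dialect in results:
        membership[f"included_{dialect}"] = membership["person_id"].isin(
            included_persons[dialect]
        )
    rows = []
    unattributed = 0
    for dialect, result in results.items():
        manifest = manifests[dialect]
        missing = union - included_persons[dialect]
        for person_id in sorted(missing):
            patids = manifest.patient_ids_for(person_id)
            reasons = sorted(
                {
                    result.reasons.get(pid)
                    for pid in patids
                    if result.reasons.get(pid) not in (None, "included")
                }
            )
            if not reasons:
                unattributed += 1
            rows.append((person_id, dialect, ";".join(reasons) or "unattributed"))
    discrepancies = pd.DataFrame(
        rows, columns=["person_id", "dialect", "attributed_reasons"]
    )
    return ConcordanceReport(
        membership=membership, discrepancies=discrepancies, unattributed=unattributed
    )
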