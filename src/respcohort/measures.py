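"""Longitudinal clinical-measure cleaning: smoking, BMI and spirometry.

GP-recorded measurements are noisy: conflicting same-day smoking codes,
physiologically impossible weights, FEV1 values entered twice.  Each
builder turns a patient's raw coded events into a chronologically
ordered, range-restricted record, and logs every dropped value with the
rule that removed it so cleaning is auditable.

Spirometry severity uses FEV1 as a percentage of a demographic
reference value (FEV1 % predicted).  Where the GP entered no percent-
predicted value on the day of an FEV1 measurement, it is derived as
FEV1 / FEV1_predicted x 100 with the predicted value from the ERS 1993
adult regression equations (sex-specific linear functions of height and
age), applied to all patients regardless of age or ethnicity.  GOLD
stages the percent-predicted value: >=80 stage 1, 50-79 stage 2,
30-49 stage 3, <30 stage 4.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import NamedTuple

import pandas as pd
import yaml

from .codelists import Codelist, Purpose
from .dateutils import as_date, completed_years
from .dialects import DialectProfile

__all__ = [
    "PlausibleRanges",
    "ERS93_COEFFICIENTS",
    "MeasureRecord",
    "build_smoking_record",
    "build_bmi_record",
    "predict_fev1",
    "build_spirometry_record",
    "gold_stage",
    "latest_in_window",
]


@dataclass(frozen=True)
class PlausibleRanges:
    """Inclusive plausible ranges used to restrict raw values.

    Defaults follow common primary-care cleaning practice for adults;
    all are configurable (e.g. from a YAML file) so they can be aligned
    with study-specific tables.
    """

    bmi: tuple[float, float] = (10.0, 80.0)
    height_m: tuple[float, float] = (1.0, 2.2)
    weight_kg: tuple[float, float] = (20.0, 250.0)
    fev1_l: tuple[float, float] = (0.1, 8.0)
    fev1_pct_predicted: tuple[float, float] = (10.0, 150.0)

    def contains(self, name: str, value: float) -> bool:
        lo, hi = getattr(self, name)
        return lo <= value <= hi

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlausibleRanges":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        return cls(**{k: tuple(v) for k, v in raw.items()})


#: Adult spirometry reference equations (litres): FEV1_pred =
#: a*height_m + b*age_years + c, per sex.
ERS93_COEFFICIENTS: dict[str, tuple[float, float, float]] = {
    "male": (4.30, -0.029, -2.49),
    "female": (3.95, -0.025, -2.60),
}


class MeasureRecord(NamedTuple):
    """A cleaned longitudinal record plus the audit log of dropped values."""

    observations: pd.DataFrame
    dropped: pd.DataFrame


def _empty_drops() -> pd.DataFrame:
    return pd.DataFrame(columns=["date", "variable", "value", "rule"])


_SMOKING_PRECEDENCE = {"current": 0, "ex": 1, "never": 2}


def build_smoking_record(events: pd.DataFrame, codelist: Codelist) -> pd.DataFrame:
    """Compile coded smoking events into a longitudinal status record.

    Codes map to {never, current, ex} via the codelist category;
    unmappable codes are ignored.  Same-day conflicts resolve by
    precedence current > ex > never, and a "never" recorded after any
    current/ex observation is re-coded to "ex" (a true never-smoker
    cannot follow an ever-smoker).

    ``events`` needs columns date, code, system.  Returns a frame with
    columns date, status, chronologically ordered, one row per day.
    """
    if codelist.purpose is not Purpose.SMOKING:
        raise ValueError(f"codelist {codelist.name!r} is not a smoking codelist")
    statuses = []
    if len(events):
        for row in events.itertuples(index=False):
            entry = codelist.lookup(str(row.code), str(row.system))
            if entry is not None and entry.category in _SMOKING_PRECEDENCE:
                statuses.append((pd.Timestamp(row.date), entry.category))
    if not statuses:
        return pd.DataFrame(columns=["date", "status"])
    frame = pd.DataFrame(statuses, columns=["date", "status"])
    frame["rank"] = frame["status"].map(_SMOKING_PRECEDENCE)
    frame = (
        frame.sort_values(["date", "rank"])
        .drop_duplicates("date", keep="first")
        .drop(columns="rank")
        .reset_index(drop=True)
    )
    ever = (frame["status"] != "never").cummax()
    frame.loc[ever & (frame["status"] == "never"), "status"] = "ex"
    return frame


def _nearest_prior(series: pd.DataFrame, when: pd.Timestamp, column: str):
    """Latest value on/before ``when`` in a date-sorted frame, else None."""
    eligible = series[series["date"] <= when]
    if eligible.empty:
        return None
    return eligible.iloc[-1][column]


def build_bmi_record(
    bmi_events: pd.DataFrame,
    weight_events: pd.DataFrame,
    height_events: pd.DataFrame,
    birth_date: date,
    profile: DialectProfile,
    ranges: PlausibleRanges | None = None,
) -> MeasureRecord:
    """Build a cleaned longitudinal BMI record.

    Recorded BMI values within the plausible range are kept as-is.  To
    improve coverage, on days with a usable weight but no recorded BMI
    a value is derived as weight / height^2 using the same-day height,
    else the nearest prior height — except in dispensed-prescription
    (dataloch_like) sources, where only recorded BMI is used.  Every
    rejected value lands in the drop log with a rule name.

    Event frames need columns date, value (kg/m^2, kg, m respectively).
    """
    ranges = ranges or PlausibleRanges()
    drops: list[tuple] = []

    def _clean(events: pd.DataFrame, variable: str, range_name: str) -> pd.DataFrame:
        if events is None or len(events) == 0:
            return pd.DataFrame(columns=["date", "value"])
        frame = events[["date", "value"]].copy()
        frame["date"] = pd.to_datetime(frame["date"])
        bad_pos = frame["value"] <= 0
        for row in frame[bad_pos].itertuples(index=False):
            drops.append((row.date, variable, row.value, "non_positive_value"))
        frame = frame[~bad_pos]
        if len(frame) == 0:
            return pd.DataFrame(columns=["date", "value"])
        out = ~frame["value"].apply(lambda v: ranges.contains(range_name, v))
        for row in frame[out].itertuples(index=False):
            drops.append((row.date, variable, row.value, f"{variable}_out_of_range"))
        return frame[~out].sort_values("date").reset_index(drop=True)

    bmi = _clean(bmi_events, "bmi", "bmi")
    observations = [
        {"date": r.date, "bmi": r.value, "provenance": "recorded"}
        for r in bmi.itertuples(index=False)
    ]

    if profile.name != "dataloch_like":
        weight = _clean(weight_events, "weight", "weight_kg")
        height = _clean(height_events, "height", "height_m")
        recorded_days = set(bmi["date"])
        for row in weight.itertuples(index=False):
            if row.date in recorded_days:
                continue
            h = _nearest_prior(height, row.date, "value")
            if h is None:
                drops.append((row.date, "weight", row.value, "no_usable_height"))
                continue
            derived = row.value / (h * h)
            if not ranges.contains("bmi", derived):
                drops.append((row.date, "derived_bmi", derived, "bmi_out_of_range"))
                continue
            observations.append(
                {"date": row.date, "bmi": derived, "provenance": "derived_from_height_weight"}
            )

    obs = pd.DataFrame(observations, columns=["date", "bmi", "provenance"])
    if len(obs):
        obs = obs.sort_values("date").drop_duplicates("date", keep="first").reset_index(drop=True)
    dropped = pd.DataFrame(drops, columns=["date", "variable", "value", "rule"])
    return MeasureRecord(obs, dropped if len(drops) else _empty_drops())


def predict_fev1(
    sex: str,
    age: float,
    height: float,
    coefficients: dict[str, tuple[float, float, float]] | None = None,
) -> float:
    """Predicted FEV1 in litres from sex, age (years) and height (m).

    Uses the adult ERS 1993 regression equations; by design these are
    applied to all ages (no 18-70 restriction) and all ethnic groups.
    """
    coefficients = coefficients or ERS93_COEFFICIENTS
    if sex not in coefficients:
        raise ValueError(f"cannot predict FEV1 for sex {sex!r}")
    if age <= 0:
        raise ValueError("age must be positive")
    h_coef, a_coef, intercept = coefficients[sex]
    return h_coef * height + a_coef * age + intercept


def gold_stage(fev1_pct_predicted: float, ranges: PlausibleRanges | None = None) -> int:
    """GOLD airflow-limitation stage from FEV1 % predicted.

    Boundaries assign to the milder stage: 80 -> stage 1, 50 -> stage 2,
    30 -> stage 3.  Applied regardless of bronchodilation status.
    """
    ranges = ranges or PlausibleRanges()
    if not ranges.contains("fev1_pct_predicted", fev1_pct_predicted):
        raise ValueError(
            f"FEV1 % predicted {fev1_pct_predicted!r} outside plausible range"
        )
    if fev1_pct_predicted >= 80:
        return 1
    if fev1_pct_predicted >= 50:
        return 2
    if fev1_pct_predicted >= 30:
        return 3
    return 4


def build_spirometry_record(
    events: pd.DataFrame,
    sex: str,
    birth_date: date,
    codelist: Codelist,
    height_record: pd.DataFrame | None = None,
    ranges: PlausibleRanges | None = None,
    coefficients: dict[str, tuple[float, float, float]] | None = None,
) -> MeasureRecord:
    """Build a cleaned longitudinal spirometry record for one patient.

    ``events`` needs columns date, code, system, value; the codelist
    categorises codes as ``fev1`` (litres), ``fev1_pct_pred`` (percent)
    or ``bronchodilation_pre``/``bronchodilation_post`` markers.

    Per day: the highest in-range FEV1 is kept; a GP-entered percent-
    predicted from the same day is attached when present, else one is
    derived from the predicted FEV1 (requiring sex and a same-day or
    nearest prior height from ``height_record`` [date, value] — when
    either is unavailable the observation keeps a missing percent-
    predicted).  Bronchodilation markers from same-day codes, else
    unknown.  GOLD stage computed wherever percent-predicted exists.
    """
    if codelist.purpose is not Purpose.SPIROMETRY:
        raise ValueError(f"codelist {codelist.name!r} is not a spirometry codelist")
    ranges = ranges or PlausibleRanges()
    coefficients = coefficients or ERS93_COEFFICIENTS
    drops: list[tuple] = []

    by_day: dict[pd.Timestamp, dict] = {}
    if len(events):
        for row in events.itertuples(index=False):
            entry = codelist.lookup(str(row.code), str(row.system))
            if entry is None:
                continue
            when = pd.Timestamp(row.date)
            day = by_day.setdefault(when, {"fev1": [], "pct": [], "bd": set()})
            if entry.category == "fev1":
                if ranges.contains("fev1_l", float(row.value)):
                    day["fev1"].append(float(row.value))
                else:
                    drops.append((when, "fev1", row.value, "fev1_out_of_range"))
            elif entry.category == "fev1_pct_pred":
                if ranges.contains("fev1_pct_predicted", float(row.value)):
                    day["pct"].append(float(row.value))
                else:
                    drops.append((when, "fev1_pct_predicted", row.value, "pct_out_of_range"))
            elif entry.category == "bronchodilation_pre":
                day["bd"].add("pre")
            elif entry.category == "bronchodilation_post":
                day["bd"].add("post")

    heights = None
    if height_record is not None and len(height_record):
        heights = height_record.copy()
        heights["date"] = pd.to_datetime(heights["date"])
        heights = heights.sort_values("date")

    observations = []
    for when in sorted(by_day):
        day = by_day[when]
        if not day["fev1"]:
            continue
        fev1 = max(day["fev1"])  # highest value where multiple recorded same day
        pct = None
        provenance = None
        predicted_out = None
        if day["pct"]:
            pct = max(day["pct"])
            provenance = "gp_entered"
        else:
            height = _nearest_prior(heights, when, "value") if heights is not None else None
            if height is not None and sex in coefficients:
                age = completed_years(birth_date, as_date(when))
                if age > 0:
                    predicted = predict_fev1(sex, age, float(height), coefficients)
                    if predicted > 0:
                        derived = fev1 / predicted * 100.0
                        if ranges.contains("fev1_pct_predicted", derived):
                            pct = derived
                            provenance = "derived"
                            predicted_out = predicted
                        else:
                            drops.append((when, "fev1_pct_predicted", derived, "pct_out_of_range"))
        if day["bd"] == {"pre"}:
            bd = "pre"
        elif day["bd"] == {"post"}:
            bd = "post"
        else:
            bd = "unknown"
        observations.append(
            {
                "date": when,
                "fev1": fev1,
                "fev1_pct_predicted": pct,
                "fev1_predicted": predicted_out,
                "pct_provenance": provenance,
                "bronchodilation": bd,
                "gold_stage": gold_stage(pct, ranges) if pct is not None else None,
            }
        )

    obs = pd.DataFrame(
        observations,
        columns=[
            "date",
            "fev1",
            "fev1_pct_predicted",
            "fev1_predicted",
            "pct_provenance",
            "bronchodilation",
            "gold_stage",
        ],
    )
    dropped = pd.DataFrame(drops, columns=["date", "variable", "value", "rule"])
    return MeasureRecord(obs, dropped if len(drops) else _empty_drops())


def latest_in_window(
    record: pd.DataFrame, index_date: date, window_start: date
) -> pd.Series | None:
    """Most recent observation with window_start <= date <= index_date
    (both bounds inclusive), or None when the window holds nothing."""
    index_date, window_start = as_date(index_date), as_date(window_start)
    if window_start > index_date:
        raise ValueError("window_start must not be after index_date")
    if record is None or len(record) == 0:
        return None
    dates = pd.to_datetime(record["date"])
    mask = (dates >= pd.Timestamp(window_start)) & (dates <= pd.Timestamp(index_date))
    if not mask.any():
        return None
    eligible = record[mask]
    return eligible.loc[pd.to_datetime(eligible["date"]).idxmax()]
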