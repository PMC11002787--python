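"""Dialect-aware demographic harmonisation.

Birth dates arrive at different granularities (year / ISO week / month /
exact) and are imputed deterministically; death dates come from a
primary mortality register with documented fallbacks; area-level
deprivation quintiles are numbered in opposite directions across
schemes and are therefore reported as descriptive labels; ethnicity is
resolved from GP codes first, topping up from hospital codes only when
the GP record is silent.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Mapping

import pandas as pd

from .codelists import Codelist, Purpose
from .dialects import BirthGranularity, DeprivationScheme, DialectProfile

__all__ = [
    "BirthInfo",
    "DeprivationRecord",
    "DeathResolution",
    "EthnicityResult",
    "DEPRIVATION_LABELS",
    "impute_birth_date",
    "resolve_death_date",
    "harmonise_deprivation",
    "derive_ethnicity",
]


@dataclass(frozen=True)
class BirthInfo:
    """Birth information at a declared granularity.

    ``value`` is a string whose format depends on the granularity:
    ``"1980"`` (year), ``"1975-W11"`` (ISO year-week), ``"1990-05"``
    (year-month) or ``"1990-05-17"`` (exact ISO date).
    """

    granularity: BirthGranularity
    value: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "granularity", BirthGranularity(self.granularity))
        try:
            self._parse()
        except Exception as exc:
            raise ValueError(
                f"birth value {self.value!r} inconsistent with granularity "
                f"{self.granularity.value!r}"
            ) from exc

    def _parse(self):
        g, v = self.granularity, self.value
        if g is BirthGranularity.YEAR:
            return int(v)
        if g is BirthGranularity.WEEK:
            year_part, week_part = v.split("-W")
            return date.fromisocalendar(int(year_part), int(week_part), 1)
        if g is BirthGranularity.MONTH:
            year_part, month_part = v.split("-")
            return date(int(year_part), int(month_part), 1)
        return date.fromisoformat(v)

    @classmethod
    def from_exact(cls, birth: date, granularity: BirthGranularity) -> "BirthInfo":
        """Coarsen an exact birth date to the given granularity."""
        granularity = BirthGranularity(granularity)
        if granularity is BirthGranularity.YEAR:
            return cls(granularity, f"{birth.year}")
        if granularity is BirthGranularity.WEEK:
            iso = birth.isocalendar()
            return cls(granularity, f"{iso.year}-W{iso.week:02d}")
        if granularity is BirthGranularity.MONTH:
            return cls(granularity, f"{birth.year}-{birth.month:02d}")
        return cls(granularity, birth.isoformat())


def impute_birth_date(info: BirthInfo, profile: DialectProfile) -> date:
    """Deterministic birth-date imputation per dialect convention.

    Year-only sources use 1 July of the birth year; week-of-birth
    sources use the Monday of the ISO week; month+year sources use the
    1st of the month.  Exact dates pass through unchanged.
    """
    if info.granularity is not profile.birth_granularity:
        raise ValueError(
            f"birth granularity {info.granularity.value!r} does not match "
            f"profile {profile.name!r} ({profile.birth_granularity.value!r})"
        )
    g = info.granularity
    if g is BirthGranularity.YEAR:
        return date(int(info.value), 7, 1)
    if g is BirthGranularity.WEEK:
        year_part, week_part = info.value.split("-W")
        return date.fromisocalendar(int(year_part), int(week_part), 1)
    if g is BirthGranularity.MONTH:
        year_part, month_part = info.value.split("-")
        return date(int(year_part), int(month_part), 1)
    return date.fromisoformat(info.value)


@dataclass(frozen=True)
class DeathResolution:
    date: date | None
    before_birth_warning: bool = False

    def __bool__(self) -> bool:
        return self.date is not None


def resolve_death_date(
    primary_record: Mapping[str, date | None] | None,
    internal_date: date | None,
    coverage_end: date,
    profile: DialectProfile,
    birth_date: date | None = None,
) -> DeathResolution:
    """Resolve a patient's date of death from the dialect's sources.

    ``primary_record`` is the national mortality register row, with keys
    ``death_date`` and ``registration_date`` (either may be None).

    * cprd_like: primary death date, else the register's registration
      date; deaths occurring after the primary register's coverage end
      are taken from the internal (GP-derived) date.
    * sail_like: the primary register (death date, else registration
      date).
    * dataloch_like: the internally derived date of death.

    Absent everywhere means the patient is considered alive.  A resolved
    death date earlier than the (imputed) birth date is retained but
    flagged as an integrity warning.
    """
    resolved: date | None = None
    if profile.name == "dataloch_like":
        resolved = internal_date
    else:
        if primary_record is not None:
            resolved = primary_record.get("death_date") or primary_record.get(
                "registration_date"
            )
        if (
            resolved is None
            and profile.name == "cprd_like"
            and internal_date is not None
            and internal_date > coverage_end
        ):
            resolved = internal_date
    warning = bool(resolved and birth_date and resolved < birth_date)
    return DeathResolution(date=resolved, before_birth_warning=warning)


@dataclass(frozen=True)
class DeprivationRecord:
    scheme: DeprivationScheme
    quintile: int
    record_date: date | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "scheme", DeprivationScheme(self.scheme))
        if not (isinstance(self.quintile, int) and 1 <= self.quintile <= 5):
            raise ValueError(f"deprivation quintile must be 1..5, got {self.quintile!r}")


# Ordered most → least deprived.
DEPRIVATION_LABELS = ("most deprived", "2", "3", "4", "least deprived")


def harmonise_deprivation(record: DeprivationRecord) -> str:
    """Map a scheme-specific quintile to a descriptive label.

    IMD numbers quintile 1 as least deprived while WIMD/SIMD number
    quintile 1 as most deprived; reporting descriptive terms instead of
    raw quintiles makes the schemes comparable.
    """
    if record.scheme is DeprivationScheme.IMD_ENGLAND_2019:
        return DEPRIVATION_LABELS[5 - record.quintile]
    return DEPRIVATION_LABELS[record.quintile - 1]


# Fallback mapping from a harmonised category to the four reporting
# schemes, used when the codelist does not carry explicit scheme columns.
_BROAD_OF = {
    "white": "White",
    "black": "Black",
    "asian": "Asian",
    "mixed": "Mixed",
    "other": "Other",
}

_SCHEME_COLUMNS = ("eth_ew2011", "eth_scot2011", "eth_harmonised", "eth_broad")


@dataclass(frozen=True)
class EthnicityResult:
    """Ethnicity of one patient under the four categorisation schemes.

    ``None`` in every field means no source held an ethnicity code; the
    broad scheme treats that as its sixth level, Missing.
    """

    ew2011: str | None
    scotland2011: str | None
    harmonised2011: str | None
    broad: str | None
    source: str | None  # "gp" | "hospital" | None

    @property
    def broad_or_missing(self) -> str:
        return self.broad if self.broad is not None else "Missing"


MISSING_ETHNICITY = EthnicityResult(None, None, None, None, None)


def _entry_schemes(entry) -> tuple[str | None, str | None, str | None, str | None]:
    if all(c in entry.extra for c in _SCHEME_COLUMNS):
        return tuple(entry.extra[c] or None for c in _SCHEME_COLUMNS)  # type: ignore[return-value]
    cat = entry.category
    if cat is None:
        return (None, None, None, None)
    broad = _BROAD_OF.get(cat.split(":")[0].split("-")[0].strip().lower(), "Other")
    return (cat, cat, cat, broad)


def _resolve_from_events(events: pd.DataFrame, codelist: Codelist):
    """Modal harmonised category; ties broken by the most recent record."""
    if events is None or len(events) == 0:
        return None
    matches = []
    for row in events.itertuples(index=False):
        entry = codelist.lookup(str(row.code), str(row.system))
        if entry is not None:
            matches.append((pd.Timestamp(row.date), entry))
    if not matches:
        return None
    counts: dict[str, int] = {}
    latest: dict[str, tuple[pd.Timestamp, object]] = {}
    for when, entry in matches:
        key = _entry_schemes(entry)[2] or "__uncategorised__"
        counts[key] = counts.get(key, 0) + 1
        if key not in latest or when >= latest[key][0]:
            latest[key] = (when, entry)
    top = max(counts.values())
    tied = [k for k, v in counts.items() if v == top]
    winner = max(tied, key=lambda k: latest[k][0])
    return latest[winner][1]


def derive_ethnicity(
    gp_events: pd.DataFrame | None,
    hospital_events: pd.DataFrame | None,
    codelist: Codelist,
) -> EthnicityResult:
    """Derive one patient's ethnicity under all four categorisation
    schemes from coded GP events, topping up with hospital events only
    when the GP record yields nothing.

    Conflicting codes are resolved by the modal harmonised category,
    with the most recent record breaking ties.  Event frames need
    columns ``date``, ``code``, ``system``.
    """
    if codelist.purpose is not Purpose.ETHNICITY:
        raise ValueError(f"codelist {codelist.name!r} is not an ethnicity codelist")
    for source, events in (("gp", gp_events), ("hospital", hospital_events)):
        entry = _resolve_from_events(events, codelist)
        if entry is not None:
            ew, scot, harm, broad = _entry_schemes(entry)
            return EthnicityResult(ew, scot, harm, broad, source)
    return MISSING_ETHNICITY
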