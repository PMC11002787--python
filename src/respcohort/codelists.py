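"""Codelists, coding systems and cross-terminology mappings.

UK primary-care databases code the same clinical concept in different
terminologies: CPRD Aurum uses proprietary medcodeids (aligned to
SNOMED-CT), Welsh and Scottish GP data use Read V2, and drugs appear as
dm+d product identifiers, BNF chapter codes or ATC codes depending on
the source.  Phenotyping a disease consistently across sources means
carrying one codelist per concept with entries in every system and a
relation for translating between systems.

A diagnosis code is *incident* if it can mark a new diagnosis and
*prevalent* if it indicates the disease is (still) present; disease
management codes (annual reviews, monitoring) are prevalent only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from types import MappingProxyType
from typing import Iterable, Mapping

from .errors import SchemaError, ValidationError

__all__ = [
    "System",
    "Purpose",
    "EventClass",
    "CodeEntry",
    "Codelist",
    "CodeMapping",
    "load_codelist",
    "load_mapping",
    "write_codelist",
    "write_mapping",
    "translate_code",
    "classify_event_code",
]


class System(str, Enum):
    """Coding systems used across the supported source dialects."""

    MEDCODE = "medcode"
    SNOMED_CONCEPT = "snomed_concept"
    READ_V2 = "read_v2"
    DMD = "dmd"
    BNF = "bnf"
    ATC = "atc"


class Purpose(str, Enum):
    DIAGNOSIS = "diagnosis"
    MEDICATION = "medication"
    ETHNICITY = "ethnicity"
    SMOKING = "smoking"
    BMI = "bmi"
    SPIROMETRY = "spirometry"
    ILD_SUBTYPE = "ild_subtype"


class EventClass(str, Enum):
    INCIDENT_AND_PREVALENT = "incident_and_prevalent"
    PREVALENT_ONLY = "prevalent_only"
    NOT_IN_LIST = "not_in_list"


_REQUIRED_COLUMNS = ("code", "system", "description", "incident", "prevalent", "category")


def _parse_bool(raw: str, column: str, path: object) -> bool:
    value = raw.strip().lower()
    if value in {"true", "1", "yes"}:
        return True
    if value in {"false", "0", "no", ""}:
        return False
    raise ValidationError(f"{path}: cannot parse boolean {raw!r} in column {column!r}")


@dataclass(frozen=True)
class CodeEntry:
    """One terminology code with its incident/prevalent classification.

    ``category`` carries an optional label (drug class, ILD subtype,
    smoking status, ethnicity category ...).  ``extra`` holds any further
    columns found in the source file, e.g. the four ethnicity
    categorisation schemes.
    """

    code: str
    system: System
    description: str = ""
    incident: bool = False
    prevalent: bool = False
    category: str | None = None
    extra: Mapping[str, str] = field(default_factory=lambda: MappingProxyType({}))

    def __post_init__(self) -> None:
        if not self.code:
            raise ValidationError("CodeEntry.code must be non-empty")
        object.__setattr__(self, "system", System(self.system))
        object.__setattr__(self, "extra", MappingProxyType(dict(self.extra)))

    def __hash__(self) -> int:  # extra is informational, not identity
        return hash((self.code, self.system, self.incident, self.prevalent, self.category))


@dataclass(frozen=True)
class Codelist:
    """A named, purpose-typed set of code entries.

    Diagnosis codelists must flag every entry incident and/or prevalent;
    category codelists (ethnicity, smoking, ...) may leave both false.
    ``(code, system)`` is unique within a codelist.
    """

    name: str
    purpose: Purpose
    entries: tuple[CodeEntry, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "purpose", Purpose(self.purpose))
        object.__setattr__(self, "entries", tuple(self.entries))
        if not self.entries:
            raise ValidationError(f"codelist {self.name!r} is empty")
        seen: set[tuple[str, System]] = set()
        for entry in self.entries:
            key = (entry.code, entry.system)
            if key in seen:
                raise ValidationError(
                    f"codelist {self.name!r}: duplicate code {entry.code!r} "
                    f"in system {entry.system.value!r}"
                )
            seen.add(key)
            if self.purpose is Purpose.DIAGNOSIS and not (entry.incident or entry.prevalent):
                raise ValidationError(
                    f"codelist {self.name!r}: diagnosis entry {entry.code!r} must be "
                    "incident and/or prevalent"
                )
        object.__setattr__(
            self, "_index", MappingProxyType({(e.code, e.system): e for e in self.entries})
        )

    def lookup(self, code: str, system: System | str) -> CodeEntry | None:
        return self._index.get((code, System(system)))

    def codes(self, system: System | str | None = None) -> set[str]:
        system = None if system is None else System(system)
        return {e.code for e in self.entries if system is None or e.system is system}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


class CodeMapping:
    """A cross-terminology relation of (source_system, source_code) →
    (target_system, target_code) rows.

    The relation is many-to-many in both directions.  Unmapped codes are
    simply absent; translation of an absent code yields the empty set.
    Multi-hop chains (dm+d → ATC → Read) are expressed by composing two
    single-hop translations.
    """

    def __init__(self, rows: Iterable[tuple[System | str, str, System | str, str]]):
        index: dict[tuple[System, str, System], set[str]] = {}
        canonical: set[tuple[System, str, System, str]] = set()
        for src_sys, src_code, tgt_sys, tgt_code in rows:
            src_sys, tgt_sys = System(src_sys), System(tgt_sys)
            canonical.add((src_sys, src_code, tgt_sys, tgt_code))
            index.setdefault((src_sys, src_code, tgt_sys), set()).add(tgt_code)
        self.rows: frozenset[tuple[System, str, System, str]] = frozenset(canonical)
        self._index = index

    def translate(self, code: str, from_system: System | str, to_system: System | str) -> set[str]:
        from_system, to_system = System(from_system), System(to_system)
        if from_system is to_system:
            raise ValueError("from_system and to_system must differ")
        return set(self._index.get((from_system, code, to_system), ()))

    def __len__(self) -> int:
        return len(self.rows)


def translate_code(
    code: str,
    from_system: System | str,
    to_system: System | str,
    mapping: CodeMapping,
) -> set[str]:
    """All target codes reachable from ``code`` in one mapping hop.

    Transitive chains (e.g. dm+d → ATC → Read, the route the licensed
    drug-dictionary tables take) are performed by composing two calls.
    """
    return mapping.translate(code, from_system, to_system)


def classify_event_code(
    code: str, system: System | str, codelist: Codelist
) -> EventClass:
    """Classify a clinical event code against a diagnosis codelist.

    Diagnostic codes are both incident and prevalent; disease-management
    codes are prevalent only; anything else is not in the list.
    """
    if codelist.purpose is not Purpose.DIAGNOSIS:
        raise ValueError(f"codelist {codelist.name!r} is not a diagnosis codelist")
    entry = codelist.lookup(code, system)
    if entry is None:
        return EventClass.NOT_IN_LIST
    if entry.incident:
        return EventClass.INCIDENT_AND_PREVALENT
    return EventClass.PREVALENT_ONLY


def load_codelist(path: str | Path, purpose: Purpose | str) -> Codelist:
    """Load a codelist from a UTF-8 CSV with header row.

    Required columns: code, system, description, incident, prevalent,
    category.  Booleans are the literals "true"/"false"; additional
    columns are preserved on each entry's ``extra`` mapping.  Readers
    tolerate quoted fields and CRLF line endings.
    """
    path = Path(path)
    purpose = Purpose(purpose)
    with open(path, newline="", encoding="utf-8-sig") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty codelist file")
        missing = [c for c in _REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
        entries = []
        for row in reader:
            extra = {
                k: v for k, v in row.items() if k not in _REQUIRED_COLUMNS and k is not None
            }
            entries.append(
                CodeEntry(
                    code=(row["code"] or "").strip(),
                    system=System((row["system"] or "").strip()),
                    description=(row["description"] or "").strip(),
                    incident=_parse_bool(row["incident"] or "", "incident", path),
                    prevalent=_parse_bool(row["prevalent"] or "", "prevalent", path),
                    category=(row["category"] or "").strip() or None,
                    extra=extra,
                )
            )
    if not entries:
        raise ValidationError(f"{path}: codelist file has no rows")
    return Codelist(name=path.stem, purpose=purpose, entries=tuple(entries))


def load_mapping(path: str | Path) -> CodeMapping:
    """Load a cross-terminology mapping from CSV with columns
    (source_system, source_code, target_system, target_code)."""
    path = Path(path)
    required = ("source_system", "source_code", "target_system", "target_code")
    with open(path, newline="", encoding="utf-8-sig") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty mapping file")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
        rows = [
            (
                System(row["source_system"].strip()),
                row["source_code"].strip(),
                System(row["target_system"].strip()),
                row["target_code"].strip(),
            )
            for row in reader
        ]
    return CodeMapping(rows)


def write_codelist(codelist: Codelist, path: str | Path) -> Path:
    """Write a codelist in the CSV interchange schema (extra columns included)."""
    path = Path(path)
    extra_cols = sorted({k for e in codelist.entries for k in e.extra})
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(list(_REQUIRED_COLUMNS) + extra_cols)
        for e in codelist.entries:
            writer.writerow(
                [
                    e.code,
                    e.system.value,
                    e.description,
                    "true" if e.incident else "false",
                    "true" if e.prevalent else "false",
                    e.category or "",
                ]
                + [e.extra.get(col, "") for col in extra_cols]
            )
    return path


def write_mapping(mapping: CodeMapping, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["source_system", "source_code", "target_system", "target_code"])
        for src_sys, src_code, tgt_sys, tgt_code in sorted(
            mapping.rows, key=lambda r: (r[0].value, r[1], r[2].value, r[3])
        ):
            writer.writerow([src_sys.value, src_code, tgt_sys.value, tgt_code])
    return path
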