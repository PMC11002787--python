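"""Bundle and manifest serialisation: a directory of CSV tables plus a
JSON admin/manifest sidecar."""

from __future__ import annotations

import json
from dataclasses import asdict
from datetime import date
from pathlib import Path

import pandas as pd

from .latent import LatentPerson
from .render import EHRBundle, TruthManifest

__all__ = ["write_bundle", "read_bundle", "write_manifest", "read_manifest"]


def _json_default(value):
    if isinstance(value, date):
        return value.isoformat()
    raise TypeError(f"not JSON serialisable: {type(value)}")


def write_bundle(bundle: EHRBundle, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in bundle.table_names():
        getattr(bundle, name).to_csv(directory / f"{name}.csv", index=False)
    meta = {"profile_name": bundle.profile_name, "admin": dict(bundle.admin)}
    (directory / "bundle.json").write_text(
        json.dumps(meta, default=_json_default, indent=2)
    )
    return directory


def read_bundle(directory: str | Path) -> EHRBundle:
    directory = Path(directory)
    meta = json.loads((directory / "bundle.json").read_text())
    tables = {}
    date_columns = {
        "registrations": ["start", "end"],
        "clinical_events": ["date"],
        "prescriptions": ["date"],
        "hospital_events": ["date"],
        "deaths": ["death_date", "registration_date", "internal_date"],
        "deprivation": ["record_date"],
    }
    for name in (
        "patients",
        "registrations",
        "clinical_events",
        "prescriptions",
        "deaths",
        "deprivation",
        "hospital_events",
    ):
        frame = pd.read_csv(directory / f"{name}.csv", dtype={"patient_id": str})
        if name == "patients" and "birth" in frame.columns:
            frame["birth"] = frame["birth"].astype(str)
        for column in date_columns.get(name, []):
            if column in frame.columns:
                frame[column] = pd.to_datetime(frame[column])
        tables[name] = frame
    admin = {
        key: date.fromisoformat(value) if isinstance(value, str) and len(value) == 10 else value
        for key, value in meta["admin"].items()
    }
    return EHRBundle(profile_name=meta["profile_name"], admin=admin, **tables)


def write_manifest(manifest: TruthManifest, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "id_map": manifest.id_map,
        "persons": [asdict(person) for person in manifest.persons],
    }
    path.write_text(json.dumps(payload, default=_json_default))
    return path


def _parse_date(value):
    return None if value is None else date.fromisoformat(value)


def read_manifest(path: str | Path) -> TruthManifest:
    payload = json.loads(Path(path).read_text())
    persons = []
    for raw in payload["persons"]:
        persons.append(
            LatentPerson(
                person_id=raw["person_id"],
                true_birth_date=_parse_date(raw["true_birth_date"]),
                sex=raw["sex"],
                true_death_date=_parse_date(raw["true_death_date"]),
                disease_status=raw["disease_status"],
                true_onset_date={
                    k: _parse_date(v) for k, v in raw["true_onset_date"].items()
                },
                height=raw["height"],
                ethnicity_broad=raw["ethnicity_broad"],
                ethnicity_concept=raw["ethnicity_concept"],
                deprivation_level=raw["deprivation_level"],
                practice_moves=[_parse_date(d) for d in raw["practice_moves"]],
                registrations=[
                    (_parse_date(s), _parse_date(e)) for s, e in raw["registrations"]
                ],
                diagnosis_events=[
                    (_parse_date(d), disease, concept)
                    for d, disease, concept in raw["diagnosis_events"]
                ],
                smoking_observations=[
                    (_parse_date(d), s) for d, s in raw["smoking_observations"]
                ],
                bmi_observations=[(_parse_date(d), v) for d, v in raw["bmi_observations"]],
                height_observation=(
                    None
                    if raw["height_observation"] is None
                    else (
                        _parse_date(raw["height_observation"][0]),
                        raw["height_observation"][1],
                    )
                ),
                spirometry_observations=[
                    (_parse_date(d), f, p, b)
                    for d, f, p, b in raw["spirometry_observations"]
                ],
                ethnicity_gp_date=_parse_date(raw["ethnicity_gp_date"]),
                ethnicity_hospital_date=_parse_date(raw["ethnicity_hospital_date"]),
                prescriptions=[(_parse_date(d), k) for d, k in raw["prescriptions"]],
                quality_valid=raw["quality_valid"],
            )
        )
    return TruthManifest(persons=persons, id_map=payload["id_map"])
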