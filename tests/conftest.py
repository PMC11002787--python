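"""Shared fixtures: synthetic vocabulary and a small zero-noise world
rendered into all three dialects."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from respcohort.dialects import PROFILES
from respcohort.synth import (
    GenerationParams,
    generate_population,
    render_dialect,
    vocab,
)

DIALECTS = ("cprd_like", "sail_like", "dataloch_like")
DISEASES = ("asthma", "copd", "ild")


@pytest.fixture(scope="session")
def codelists():
    return vocab.default_codelists()


@pytest.fixture(scope="session")
def mapping():
    return vocab.default_mapping()


@pytest.fixture(scope="session")
def small_params():
    return GenerationParams(n=600)


@pytest.fixture(scope="session")
def small_population(small_params):
    return generate_population(small_params, seed=11)


@pytest.fixture(scope="session")
def small_world(small_population, small_params, codelists, mapping):
    """Zero-noise renders of one latent population in every dialect."""
    world = {}
    for dialect in DIALECTS:
        bundle, manifest = render_dialect(
            small_population,
            PROFILES[dialect],
            codelists,
            mapping,
            seed=23,
            params=small_params,
        )
        world[dialect] = (bundle, manifest)
    return world


def make_bundle(
    profile_name: str,
    patients: list[dict],
    registrations: list[dict],
    clinical_events: list[dict] | None = None,
    prescriptions: list[dict] | None = None,
    deaths: list[dict] | None = None,
    deprivation: list[dict] | None = None,
    hospital_events: list[dict] | None = None,
    admin: dict | None = None,
):
    """Hand-rolled minimal bundle for targeted criterion tests."""
    from respcohort.synth.render import EHRBundle

    def frame(rows, columns):
        f = pd.DataFrame(rows or [], columns=columns)
        for column in ("date", "start", "end", "death_date", "registration_date",
                       "internal_date", "record_date"):
            if column in f.columns:
                f[column] = pd.to_datetime(f[column])
        return f

    defaults = {"acceptable": True, "linkage_eligible": True, "region": "London"}
    patient_rows = [{**defaults, **p} for p in patients]
    return EHRBundle(
        profile_name=profile_name,
        patients=frame(
            patient_rows,
            ["patient_id", "sex", "birth", "acceptable", "linkage_eligible", "region"],
        ),
        registrations=frame(registrations, ["patient_id", "start", "end"]),
        clinical_events=frame(
            clinical_events, ["patient_id", "date", "code", "system", "value"]
        ),
        prescriptions=frame(prescriptions, ["patient_id", "date", "code", "system"]),
        deaths=frame(
            deaths, ["patient_id", "death_date", "registration_date", "internal_date"]
        ),
        deprivation=frame(deprivation, ["patient_id", "scheme", "quintile", "record_date"]),
        hospital_events=frame(hospital_events, ["patient_id", "date", "code", "system"]),
        admin=admin
        or {
            "extraction_date": pd.Timestamp("2022-03-07").date(),
            "last_collection_date": pd.Timestamp("2022-02-01").date(),
            "ons_coverage_end": pd.Timestamp("2021-03-31").date(),
        },
    )
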