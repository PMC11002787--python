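"""Follow-up computation, diagnosis-date derivation and the inclusion/
exclusion cascade, checked against hand oracles and the truth manifest."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from respcohort.codelists import EventClass, System
from respcohort.cohort import (
    CohortSpec,
    apply_cohort_criteria,
    classify_ild_subtypes,
    compute_followup,
    derive_diagnosis_dates,
    restrict_events_to_registration,
)
from respcohort.dialects import CPRD_LIKE, DATALOCH_LIKE, PROFILES, SAIL_LIKE
from respcohort.errors import IntegrityError, ValidationError
from respcohort.synth import vocab

from conftest import DIALECTS, DISEASES, make_bundle


def _regs(rows):
    frame = pd.DataFrame(rows, columns=["patient_id", "start", "end"])
    frame["start"] = pd.to_datetime(frame["start"])
    frame["end"] = pd.to_datetime(frame["end"])
    return frame


def _events(rows):
    frame = pd.DataFrame(rows, columns=["patient_id", "date", "code", "system"])
    frame["date"] = pd.to_datetime(frame["date"])
    return frame


class TestRestrictEventsToRegistration:
    def test_event_outside_registration_dropped_in_per_registration_source(self):
        events = _events([("a", "2009-06-01", "c", "medcode")])
        regs = _regs([("a", "2010-01-01", "2015-01-01")])
        assert len(restrict_events_to_registration(events, regs, CPRD_LIKE)) == 0

    def test_event_between_registrations_retained_elsewhere(self):
        events = _events([("a", "2006-06-01", "c", "read_v2")])
        regs = _regs([("a", "2000-01-01", "2005-01-01"), ("a", "2007-01-01", None)])
        kept = restrict_events_to_registration(events, regs, SAIL_LIKE)
        assert len(kept) == 1

    def test_event_inside_window_retained(self):
        events = _events([("a", "2012-06-01", "c", "medcode")])
        regs = _regs([("a", "2010-01-01", "2015-01-01")])
        assert len(restrict_events_to_registration(events, regs, CPRD_LIKE)) == 1

    def test_unknown_patient_is_integrity_error(self):
        events = _events([("ghost", "2012-06-01", "c", "medcode")])
        regs = _regs([("a", "2010-01-01", "2015-01-01")])
        with pytest.raises(IntegrityError):
            restrict_events_to_registration(events, regs, CPRD_LIKE)


class TestComputeFollowup:
    ADMIN = {
        "last_collection_date": date(2019, 1, 1),
        "extraction_date": date(2022, 3, 7),
    }

    def test_per_registration_end_is_earliest_of_candidates(self):
        regs = _regs([("a", "2005-01-01", "2020-03-01")])
        fu = compute_followup("a", regs, date(2018, 5, 1), CPRD_LIKE, self.ADMIN)
        assert fu.start == date(2005, 1, 1)
        assert fu.end == date(2018, 5, 1)
        assert fu.valid

    def test_per_person_open_registration_ends_at_extraction(self):
        regs = _regs([("a", "2000-01-01", "2005-06-30"), ("a", "2007-01-01", None)])
        fu = compute_followup("a", regs, None, SAIL_LIKE, self.ADMIN)
        assert fu.start == date(2000, 1, 1)
        assert fu.end == date(2022, 3, 7)

    def test_death_before_registration_flags_invalid(self):
        regs = _regs([("a", "2010-01-01", None)])
        fu = compute_followup("a", regs, date(2005, 1, 1), CPRD_LIKE, self.ADMIN)
        assert not fu.valid

    def test_no_registrations_rejected(self):
        with pytest.raises(ValidationError):
            compute_followup("a", _regs([]), None, SAIL_LIKE, self.ADMIN)


class TestDeriveDiagnosisDates:
    I = EventClass.INCIDENT_AND_PREVALENT
    P = EventClass.PREVALENT_ONLY

    def test_first_year_mention_masks_incidence(self):
        earliest, incidence = derive_diagnosis_dates(
            [(date(2010, 6, 1), self.I)], date(2010, 1, 1)
        )
        assert earliest == date(2010, 6, 1)
        assert incidence is None

    def test_single_incident_event_outside_first_year(self):
        earliest, incidence = derive_diagnosis_dates(
            [(date(2010, 6, 1), self.I)], date(2005, 3, 1)
        )
        assert earliest == incidence == date(2010, 6, 1)

    def test_prevalent_mention_precedes_incidence(self):
        earliest, incidence = derive_diagnosis_dates(
            [(date(2008, 2, 1), self.P), (date(2009, 9, 1), self.I)],
            date(2005, 1, 1),
        )
        assert earliest == date(2008, 2, 1)
        assert incidence == date(2009, 9, 1)

    def test_boundary_one_calendar_year_not_masked(self):
        earliest, incidence = derive_diagnosis_dates(
            [(date(2011, 1, 1), self.I)], date(2010, 1, 1)
        )
        assert incidence == date(2011, 1, 1)  # [start, start+1y) is half-open

    def test_prevalent_only_events_yield_no_incidence(self):
        _, incidence = derive_diagnosis_dates(
            [(date(2010, 1, 1), self.P)], date(2005, 1, 1)
        )
        assert incidence is None

    def test_empty_events_rejected(self):
        with pytest.raises(ValidationError):
            derive_diagnosis_dates([], date(2010, 1, 1))

    def test_against_brute_force_oracle(self):
        """Independent scan over randomized event lists, including the
        first-year masking rule."""
        rng = np.random.default_rng(2024)
        base = date(2000, 1, 1)
        for _ in range(400):
            fu_start = base + timedelta(days=int(rng.integers(0, 4000)))
            n_events = int(rng.integers(1, 8))
            events = [
                (
                    base + timedelta(days=int(rng.integers(0, 7000))),
                    self.I if rng.random() < 0.5 else self.P,
                )
                for _ in range(n_events)
            ]
            # oracle: explicit scan, independent date arithmetic
            oracle_earliest = min(d for d, _ in events)
            incident = [d for d, c in events if c is self.I]
            oracle_doi = min(incident) if incident else None
            try:
                year_later = fu_start.replace(year=fu_start.year + 1)
            except ValueError:
                year_later = fu_start.replace(year=fu_start.year + 1, day=28)
            if oracle_earliest < year_later:
                oracle_doi = None
            assert derive_diagnosis_dates(events, fu_start) == (
                oracle_earliest,
                oracle_doi,
            )


def _dx(concept, system=System.MEDCODE):
    return vocab.clinical_code(concept, system)


class TestApplyCohortCriteria:
    """Targeted hand-built bundles exercising each criterion."""

    def _one_patient_bundle(self, *, sex="male", birth="1950", events=None,
                            death=None, profile_name="cprd_like"):
        return make_bundle(
            profile_name,
            patients=[{"patient_id": "a", "sex": sex, "birth": birth}],
            registrations=[{"patient_id": "a", "start": "1950-07-01", "end": None}],
            clinical_events=[
                {"patient_id": "a", "date": d, "code": c, "system": "medcode",
                 "value": None}
                for d, c in (events or [])
            ],
            deaths=(
                [{"patient_id": "a", "death_date": death, "registration_date": None,
                  "internal_date": None}]
                if death
                else None
            ),
        )

    def test_copd_code_before_age_35_not_a_valid_event(self, codelists):
        # born 1980 (imputed 1980-07-01), COPD code at age 34
        bundle = self._one_patient_bundle(
            birth="1980", events=[("2014-08-01", _dx("copd_dx1"))]
        )
        bundle.registrations.loc[0, "start"] = pd.Timestamp("1980-07-01")
        result = apply_cohort_criteria(
            bundle, CohortSpec.for_disease("copd"), codelists["copd"], CPRD_LIKE
        )
        assert len(result.members) == 0
        assert result.tally["no_valid_disease_event"] == 1

    def test_death_before_2004_excluded(self, codelists):
        bundle = self._one_patient_bundle(
            events=[("2001-05-01", _dx("asthma_dx1"))], death="2003-06-01"
        )
        bundle.registrations.loc[0, "end"] = pd.Timestamp("2003-06-01")
        result = apply_cohort_criteria(
            bundle, CohortSpec.for_disease("asthma"), codelists["asthma"], CPRD_LIKE
        )
        assert result.tally["not_alive_and_registered_from_2004"] == 1

    def test_event_before_imputed_birth_invalid(self, codelists):
        bundle = self._one_patient_bundle(
            birth="1980", events=[("1980-03-01", _dx("asthma_dx1"))]
        )
        result = apply_cohort_criteria(
            bundle, CohortSpec.for_disease("asthma"), codelists["asthma"], CPRD_LIKE
        )
        assert result.tally["no_valid_disease_event"] == 1

    def test_unknown_sex_excluded_first(self, codelists):
        bundle = self._one_patient_bundle(
            sex="unknown", events=[("2010-01-01", _dx("asthma_dx1"))]
        )
        result = apply_cohort_criteria(
            bundle, CohortSpec.for_disease("asthma"), codelists["asthma"], CPRD_LIKE
        )
        assert result.tally["sex_not_male_female"] == 1

    def test_event_after_latest_event_date_invalid(self, codelists):
        bundle = self._one_patient_bundle(events=[("2020-06-01", _dx("asthma_dx1"))])
        result = apply_cohort_criteria(
            bundle, CohortSpec.for_disease("asthma"), codelists["asthma"], CPRD_LIKE
        )
        assert len(result.members) == 0

    def test_member_fields_and_incidence_masking(self, codelists):
        bundle = self._one_patient_bundle(
            events=[("2008-02-01", _dx("asthma_rev")), ("2009-09-01", _dx("asthma_dx1"))]
        )
        result = apply_cohort_criteria(
            bundle, CohortSpec.for_disease("asthma"), codelists["asthma"], CPRD_LIKE
        )
        member = result.members.iloc[0]
        assert member["earliest_mention"] == pd.Timestamp("2008-02-01")
        assert member["date_of_incidence"] == pd.Timestamp("2009-09-01")
        assert member["age_at_earliest_mention"] == 57


class TestClassifyIldSubtypes:
    def test_narrow_ipf_implies_broad(self, codelists):
        events = _events([("a", "2010-01-01", _dx("ild_ipf_narrow"), "medcode")])
        flags = classify_ild_subtypes(events, codelists["ild_subtype"])
        assert flags["a"] >= {"ipf_narrow", "ipf_broad"}

    def test_sarcoidosis_is_autoimmune_related(self, codelists):
        events = _events([("a", "2010-01-01", _dx("ild_sarcoid"), "medcode")])
        assert classify_ild_subtypes(events, codelists["ild_subtype"])["a"] == {
            "autoimmune_related"
        }

    def test_multiple_codes_yield_multiple_flags_no_final_label(self, codelists):
        events = _events(
            [
                ("a", "2010-01-01", _dx("ild_ipf_narrow"), "medcode"),
                ("a", "2012-01-01", _dx("ild_hp"), "medcode"),
            ]
        )
        flags = classify_ild_subtypes(events, codelists["ild_subtype"])
        assert flags["a"] == {"ipf_narrow", "ipf_broad", "exposure_related"}


class TestRecoveryOnSyntheticWorld:
    @pytest.mark.parametrize("dialect", DIALECTS)
    @pytest.mark.parametrize("disease", DISEASES)
    def test_exact_truth_recovery_at_zero_missingness(
        self, small_world, codelists, dialect, disease
    ):
        bundle, manifest = small_world[dialect]
        spec = CohortSpec.for_disease(disease)
        result = apply_cohort_criteria(
            bundle, spec, codelists[disease], PROFILES[dialect]
        )
        recovered = manifest.persons_of(result.patient_ids)
        expected = manifest.expected_person_ids(
            disease, min_event_age_years=spec.min_event_age_years
        )
        assert recovered == expected
        assert result.conserved()

    def test_raising_min_age_never_adds_members(self, small_world, codelists):
        bundle, _ = small_world["sail_like"]
        members = {}
        for age in (0, 35, 50, 70):
            spec = CohortSpec(disease="copd", min_event_age_years=age)
            result = apply_cohort_criteria(bundle, spec, codelists["copd"], SAIL_LIKE)
            members[age] = result.patient_ids
        assert members[70] <= members[50] <= members[35] <= members[0]

    def test_diagnosis_dates_match_brute_force_scan(self, small_world, codelists):
        """Member-level oracle: scan every clinical event directly."""
        bundle, _ = small_world["sail_like"]
        spec = CohortSpec.for_disease("asthma")
        result = apply_cohort_criteria(bundle, spec, codelists["asthma"], SAIL_LIKE)
        lookup = {
            (e.code, e.system.value): e.incident for e in codelists["asthma"]
        }
        events = bundle.clinical_events
        for member in result.members.itertuples(index=False):
            rows = events[events["patient_id"] == member.patient_id]
            birth = member.birth_date_imputed
            death = member.death_date
            dated = []
            for row in rows.itertuples(index=False):
                incident = lookup.get((row.code, row.system))
                if incident is None:
                    continue
                when = row.date
                age = when.year - birth.year - (
                    (when.month, when.day) < (birth.month, birth.day)
                )
                if when < birth or when > pd.Timestamp("2019-12-31") or age < 0:
                    continue
                if not pd.isna(death) and when > death:
                    continue
                dated.append((when, incident))
            oracle_earliest = min(d for d, _ in dated)
            incident_dates = [d for d, inc in dated if inc]
            oracle_doi = min(incident_dates) if incident_dates else None
            start = member.followup_start
            if oracle_earliest < start + pd.DateOffset(years=1):
                oracle_doi = None
            assert member.earliest_mention == oracle_earliest
            if oracle_doi is None:
                assert pd.isna(member.date_of_incidence)
            else:
                assert member.date_of_incidence == oracle_doi
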