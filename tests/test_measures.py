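"""Smoking/BMI/spirometry cleaning, FEV1 prediction and GOLD staging."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from respcohort.codelists import System
from respcohort.dialects import CPRD_LIKE, DATALOCH_LIKE
from respcohort.measures import (
    PlausibleRanges,
    build_bmi_record,
    build_smoking_record,
    build_spirometry_record,
    gold_stage,
    latest_in_window,
    predict_fev1,
)
from respcohort.synth import vocab

MC = System.MEDCODE


def _smoke_events(rows):
    return pd.DataFrame(
        [
            (d, vocab.clinical_code(f"smok_{status}", MC), "medcode")
            for d, status in rows
        ],
        columns=["date", "code", "system"],
    )


def _value_events(rows, concept):
    return pd.DataFrame(
        [(d, vocab.clinical_code(concept, MC), "medcode", v) for d, v in rows],
        columns=["date", "code", "system", "value"],
    )


class TestBuildSmokingRecord:
    def test_consistent_sequence_passes_through(self, codelists):
        record = build_smoking_record(
            _smoke_events([("2010-01-01", "never"), ("2012-01-01", "current")]),
            codelists["smoking"],
        )
        assert list(record["status"]) == ["never", "current"]

    def test_never_after_ever_recoded_to_ex(self, codelists):
        record = build_smoking_record(
            _smoke_events([("2010-01-01", "current"), ("2014-01-01", "never")]),
            codelists["smoking"],
        )
        assert list(record["status"]) == ["current", "ex"]

    def test_empty_input_empty_record(self, codelists):
        record = build_smoking_record(
            pd.DataFrame(columns=["date", "code", "system"]), codelists["smoking"]
        )
        assert len(record) == 0

    def test_same_day_conflict_current_wins(self, codelists):
        record = build_smoking_record(
            _smoke_events([("2010-01-01", "ex"), ("2010-01-01", "current")]),
            codelists["smoking"],
        )
        assert list(record["status"]) == ["current"]

    @settings(max_examples=150, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 5000), st.sampled_from(["never", "current", "ex"])
            ),
            min_size=0,
            max_size=12,
        )
    )
    def test_no_never_after_ever_property(self, codelists, raw):
        events = _smoke_events(
            [(str(date(2000, 1, 1) + pd.Timedelta(days=d).to_pytimedelta()), s)
             for d, s in raw]
        )
        record = build_smoking_record(events, codelists["smoking"])
        seen_ever = False
        for status in record["status"]:
            if status in ("current", "ex"):
                seen_ever = True
            elif seen_ever:
                pytest.fail("'never' recorded after an ever-smoker status")


class TestBuildBmiRecord:
    def test_recorded_bmi_kept(self, codelists):
        record, _ = build_bmi_record(
            _value_events([("2010-01-01", 27.5)], "obs_bmi"),
            _value_events([], "obs_weight"),
            _value_events([], "obs_height"),
            date(1960, 1, 1),
            CPRD_LIKE,
        )
        assert record.iloc[0]["bmi"] == 27.5
        assert record.iloc[0]["provenance"] == "recorded"

    def test_bmi_derived_from_weight_and_height(self, codelists):
        record, _ = build_bmi_record(
            _value_events([], "obs_bmi"),
            _value_events([("2010-01-01", 80.0)], "obs_weight"),
            _value_events([("2009-01-01", 1.80)], "obs_height"),
            date(1960, 1, 1),
            CPRD_LIKE,
        )
        assert record.iloc[0]["provenance"] == "derived_from_height_weight"
        assert record.iloc[0]["bmi"] == pytest.approx(24.69, abs=0.005)

    def test_dataloch_never_derives(self, codelists):
        record, _ = build_bmi_record(
            _value_events([], "obs_bmi"),
            _value_events([("2010-01-01", 80.0)], "obs_weight"),
            _value_events([("2009-01-01", 1.80)], "obs_height"),
            date(1960, 1, 1),
            DATALOCH_LIKE,
        )
        assert len(record) == 0

    def test_out_of_range_bmi_dropped_and_logged(self, codelists):
        record, drops = build_bmi_record(
            _value_events([("2010-01-01", 500.0)], "obs_bmi"),
            _value_events([], "obs_weight"),
            _value_events([], "obs_height"),
            date(1960, 1, 1),
            CPRD_LIKE,
        )
        assert len(record) == 0
        assert list(drops["rule"]) == ["bmi_out_of_range"]

    def test_non_positive_height_dropped_with_rule(self, codelists):
        _, drops = build_bmi_record(
            _value_events([], "obs_bmi"),
            _value_events([("2010-01-01", 80.0)], "obs_weight"),
            _value_events([("2009-01-01", -1.7)], "obs_height"),
            date(1960, 1, 1),
            CPRD_LIKE,
        )
        assert "non_positive_value" in set(drops["rule"])
        assert "no_usable_height" in set(drops["rule"])


class TestPredictFev1:
    def test_male_reference_value(self):
        assert predict_fev1("male", 50, 1.75) == pytest.approx(3.585, abs=5e-4)

    def test_female_reference_value(self):
        assert predict_fev1("female", 40, 1.60) == pytest.approx(2.720, abs=5e-4)

    def test_pure_function(self):
        assert predict_fev1("male", 50, 1.75) == predict_fev1("male", 50, 1.75)

    def test_unknown_sex_cannot_predict(self):
        with pytest.raises(ValueError):
            predict_fev1("unknown", 50, 1.75)


class TestGoldStage:
    @pytest.mark.parametrize(
        "pct,stage", [(85, 1), (80, 1), (79.99, 2), (50, 2), (49.99, 3), (40, 3),
                      (30, 3), (29.99, 4), (15, 4)]
    )
    def test_thresholds(self, pct, stage):
        assert gold_stage(pct) == stage

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gold_stage(5.0)

    def test_stages_partition_valid_range_monotonically(self):
        grid = np.arange(10.0, 150.0, 0.25)
        stages = [gold_stage(float(x)) for x in grid]
        assert set(stages) == {1, 2, 3, 4}
        assert all(a >= b for a, b in zip(stages, stages[1:]))  # severity falls


class TestBuildSpirometryRecord:
    def _record(self, events, codelists, heights=None, sex="female",
                birth=date(1970, 1, 1)):
        return build_spirometry_record(
            events,
            sex=sex,
            birth_date=birth,
            codelist=codelists["spirometry"],
            height_record=heights,
        )

    def test_same_day_highest_fev1_kept(self, codelists):
        events = _value_events(
            [("2015-01-01", 2.1), ("2015-01-01", 2.3)], "obs_fev1"
        )
        record, _ = self._record(events, codelists)
        assert len(record) == 1
        assert record.iloc[0]["fev1"] == 2.3

    def test_derived_percent_predicted(self, codelists):
        # female aged 40 at measurement, height 1.60 m: predicted 2.720 L
        events = _value_events([("2010-06-01", 2.0)], "obs_fev1")
        heights = pd.DataFrame({"date": ["2009-01-01"], "value": [1.60]})
        record, _ = self._record(events, codelists, heights,
                                 birth=date(1970, 3, 1))
        row = record.iloc[0]
        assert row["pct_provenance"] == "derived"
        assert row["fev1_pct_predicted"] == pytest.approx(73.5, abs=0.05)

    def test_gp_entered_value_preferred_same_day(self, codelists):
        events = pd.concat(
            [
                _value_events([("2010-06-01", 2.0)], "obs_fev1"),
                _value_events([("2010-06-01", 68.0)], "obs_fev1_pct"),
            ]
        )
        heights = pd.DataFrame({"date": ["2009-01-01"], "value": [1.60]})
        record, _ = self._record(events, codelists, heights, birth=date(1970, 3, 1))
        row = record.iloc[0]
        assert row["fev1_pct_predicted"] == 68.0
        assert row["pct_provenance"] == "gp_entered"

    def test_missing_sex_keeps_observation_without_pct(self, codelists):
        events = _value_events([("2010-06-01", 2.0)], "obs_fev1")
        heights = pd.DataFrame({"date": ["2009-01-01"], "value": [1.60]})
        record, _ = self._record(events, codelists, heights, sex="unknown")
        assert len(record) == 1
        assert pd.isna(record.iloc[0]["fev1_pct_predicted"])

    def test_out_of_range_fev1_dropped_with_rule(self, codelists):
        events = _value_events([("2010-06-01", 12.0)], "obs_fev1")
        record, drops = self._record(events, codelists)
        assert len(record) == 0
        assert list(drops["rule"]) == ["fev1_out_of_range"]

    def test_bronchodilation_marker_attached(self, codelists):
        events = pd.concat(
            [
                _value_events([("2010-06-01", 2.0)], "obs_fev1"),
                _value_events([("2010-06-01", float("nan"))], "obs_bd_post"),
            ]
        )
        record, _ = self._record(events, codelists)
        assert record.iloc[0]["bronchodilation"] == "post"

    def test_derived_pct_self_consistent(self, codelists):
        events = _value_events(
            [("2008-03-01", 1.4), ("2012-07-01", 1.9), ("2016-11-01", 2.2)],
            "obs_fev1",
        )
        heights = pd.DataFrame({"date": ["2007-01-01"], "value": [1.72]})
        record, _ = self._record(events, codelists, heights, sex="male",
                                 birth=date(1955, 6, 15))
        derived = record[record["pct_provenance"] == "derived"]
        assert len(derived) == 3
        recomputed = derived["fev1"] / derived["fev1_predicted"] * 100.0
        assert (recomputed - derived["fev1_pct_predicted"]).abs().max() <= 0.01


class TestLatestInWindow:
    RECORD = pd.DataFrame(
        {"date": pd.to_datetime(["2013-05-01", "2016-02-01", "2018-09-01"]),
         "value": [1.0, 2.0, 3.0]}
    )

    def test_latest_within_window_returned(self):
        row = latest_in_window(self.RECORD, date(2019, 12, 31), date(2015, 1, 1))
        assert row["value"] == 3.0

    def test_nothing_in_window_is_missing(self):
        only_old = self.RECORD.iloc[:1]
        assert latest_in_window(only_old, date(2019, 12, 31), date(2015, 1, 1)) is None

    def test_index_date_boundary_inclusive(self):
        record = pd.DataFrame({"date": pd.to_datetime(["2019-12-31"]), "value": [9.0]})
        row = latest_in_window(record, date(2019, 12, 31), date(2015, 1, 1))
        assert row["value"] == 9.0

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            latest_in_window(self.RECORD, date(2015, 1, 1), date(2019, 12, 31))
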