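"""Cohort reading, unit conversion, scoring orchestration, results file."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bmiage import cohort, metrics
from bmiage.classify import WeightStatus
from bmiage.cohort import SubjectRecord, convert_length_in_to_cm, convert_weight_lb_to_kg
from bmiage.lms import Sex


class TestReadCohort:
    def test_reads_three_valid_rows(self, small_cohort_csv):
        records = cohort.read_cohort(small_cohort_csv)
        assert len(records) == 3
        assert records[0].sex == Sex.FEMALE and records[1].sex == Sex.MALE
        assert all(not r.flags for r in records)

    def test_reads_excel(self, tmp_path):
        path = tmp_path / "BMI_Data.xlsx"
        pd.DataFrame(
            {"ID": [1], "Sex": ["F"], "Age_y": [8.5], "Height_cm": [130.0], "Weight_kg": [28.0]}
        ).to_excel(path, index=False)
        (rec,) = cohort.read_cohort(path)
        assert rec.height_cm == 130.0

    def test_invalid_sex_flags_only_that_row(self, tmp_path):
        path = tmp_path / "c.csv"
        pd.DataFrame(
            {
                "ID": [1, 2],
                "Sex": ["X", "F"],
                "Age_y": [9.5, 9.5],
                "Height_cm": [130.0, 130.0],
                "Weight_kg": [28.0, 28.0],
            }
        ).to_csv(path, index=False)
        bad, good = cohort.read_cohort(path)
        assert any("invalid sex" in f for f in bad.flags)
        assert not good.flags

    def test_bmi_only_row_parses(self, tmp_path):
        path = tmp_path / "c.csv"
        pd.DataFrame({"ID": [1], "Sex": ["m"], "Age_y": [12.5], "BMI": [22.5]}).to_csv(
            path, index=False
        )
        (rec,) = cohort.read_cohort(path)
        assert rec.bmi_supplied == 22.5 and rec.height_cm is None

    def test_missing_required_column(self, tmp_path):
        path = tmp_path / "c.csv"
        pd.DataFrame({"ID": [1], "Age_y": [5.5], "BMI": [17.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="Sex"):
            cohort.read_cohort(path)

    def test_no_bmi_source_columns(self, tmp_path):
        path = tmp_path / "c.csv"
        pd.DataFrame({"ID": [1], "Sex": ["F"], "Age_y": [5.5]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="BMI"):
            cohort.read_cohort(path)

    def test_case_insensitive_headers(self, tmp_path):
        path = tmp_path / "c.csv"
        pd.DataFrame(
            {"id": [7], "SEX": ["F"], "age_Y": [6.5], "HEIGHT_CM": [115.0], "weight_kg": [20.0]}
        ).to_csv(path, index=False)
        (rec,) = cohort.read_cohort(path)
        assert rec.id == 7 and rec.weight_kg == 20.0


class TestUnitConversion:
    @pytest.mark.parametrize("inches, cm", [(1.0, 2.54), (0.0, 0.0), (60.0, 152.4)])
    def test_length(self, inches, cm):
        assert convert_length_in_to_cm(inches) == pytest.approx(cm, rel=1e-12)

    @pytest.mark.parametrize("lbs, kg", [(2.20462, 1.0), (0.0, 0.0)])
    def test_weight(self, lbs, kg):
        assert convert_weight_lb_to_kg(lbs) == pytest.approx(kg, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            convert_length_in_to_cm(-1.0)
        with pytest.raises(ValueError):
            convert_weight_lb_to_kg(-1.0)

    @given(st.floats(0.0, 500.0))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_identity(self, lbs):
        kg = convert_weight_lb_to_kg(lbs)
        assert kg * cohort.LB_PER_KG == pytest.approx(lbs, rel=1e-9, abs=1e-12)
        cm = convert_length_in_to_cm(lbs)  # any non-negative real
        assert cm / cohort.CM_PER_IN == pytest.approx(lbs, rel=1e-9, abs=1e-12)


class TestEffectiveBmi:
    def test_height_weight_preferred_over_supplied(self):
        rec = SubjectRecord(1, Sex.FEMALE, 10.0, height_cm=100.0, weight_kg=16.0, bmi_supplied=99.0)
        assert cohort.effective_bmi(rec) == (16.0, "computed")

    def test_supplied_fallback(self):
        rec = SubjectRecord(1, Sex.FEMALE, 10.0, bmi_supplied=22.5)
        assert cohort.effective_bmi(rec) == (22.5, "supplied")

    def test_neither_source_errors(self):
        with pytest.raises(ValueError):
            cohort.effective_bmi(SubjectRecord(1, Sex.FEMALE, 10.0))


class TestDetectMode:
    @pytest.mark.parametrize(
        "ids, expected",
        [([1, 2, 3], "cross_sectional"), ([1, 1, 2], "longitudinal"), ([1], "cross_sectional")],
    )
    def test_modes(self, ids, expected):
        records = [SubjectRecord(i, Sex.MALE, 10.0, bmi_supplied=20.0) for i in ids]
        assert cohort.detect_mode(records) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cohort.detect_mode([])


class TestComputeResults:
    def test_median_subject_scores_fiftieth(self, reference):
        age = 8.25
        _, M, _ = reference.interpolate(Sex.FEMALE, age * 12)
        rec = SubjectRecord(1, Sex.FEMALE, age, bmi_supplied=M)
        (res,) = cohort.compute_results([rec], reference)
        assert res.bmi_z == pytest.approx(0.0, abs=1e-9)
        assert res.bmi_pct == pytest.approx(50.0, abs=1e-6)
        assert res.weight_status is WeightStatus.HEALTHY
        assert res.bmi_source == "supplied"

    def test_subject_at_140pct_of_p95_is_class3(self, reference):
        age = 12.0 + 1 / 12
        L, M, S = reference.interpolate(Sex.MALE, age * 12)
        p95 = metrics.bmi_at_percentile(95.0, L, M, S)
        rec = SubjectRecord(1, Sex.MALE, age, bmi_supplied=1.4 * p95)
        (res,) = cohort.compute_results([rec], reference)
        assert res.weight_status is WeightStatus.SEVERE_3
        assert res.bmi_95 == pytest.approx(140.0, rel=1e-9)

    def test_out_of_range_age_flagged_not_fatal(self, reference):
        recs = [
            SubjectRecord(1, Sex.FEMALE, 1.0, bmi_supplied=17.0),
            SubjectRecord(2, Sex.FEMALE, 10.0, bmi_supplied=17.0),
            SubjectRecord(3, Sex.FEMALE, 20.0, bmi_supplied=17.0),  # 20 y is excluded
        ]
        results = cohort.compute_results(recs, reference)
        assert len(results) == 3  # row conservation
        assert results[0].weight_status is None and math.isnan(results[0].bmi_pct)
        assert any("outside supported range" in f for f in results[0].qc_flags)
        assert results[1].weight_status is not None
        assert results[2].weight_status is None

    def test_conflicting_sex_for_replicated_id(self, reference):
        recs = [
            SubjectRecord(1, Sex.FEMALE, 10.0, bmi_supplied=18.0),
            SubjectRecord(1, Sex.MALE, 11.0, bmi_supplied=18.5),
        ]
        results = cohort.compute_results(recs, reference)
        assert all(
            any("conflicting sex" in f for f in r.qc_flags) and r.weight_status is None
            for r in results
        )

    def test_supplied_bmi_discrepancy_flagged_but_computed_used(self, reference):
        rec = SubjectRecord(
            1, Sex.FEMALE, 9.0 + 1 / 3, height_cm=100.0, weight_kg=16.0, bmi_supplied=17.5
        )
        (res,) = cohort.compute_results([rec], reference)
        assert res.bmi_kgm2 == pytest.approx(16.0)
        assert any("disagrees" in f for f in res.qc_flags)
        assert res.weight_status is not None

    def test_whole_number_age_warns_but_scores(self, reference):
        rec = SubjectRecord(1, Sex.MALE, 9.0, bmi_supplied=18.0)
        (res,) = cohort.compute_results([rec], reference)
        assert any("whole-number age" in f for f in res.qc_flags)
        assert res.weight_status is not None


class TestWriteResults:
    def test_schema_and_round_trip(self, reference, small_cohort_csv, tmp_path):
        records = cohort.read_cohort(small_cohort_csv)
        results = cohort.compute_results(records, reference)
        out = cohort.write_results(results, tmp_path)
        assert out.name == "BMI_Results.csv"
        df = pd.read_csv(out)
        assert len(df) == len(records)
        for col in ("BMI_kgm2", "BMI_pct", "BMI_z", "BMI_95", "Weight_status"):
            assert col in df.columns
        # status strings are exactly the six canonical phrases
        allowed = {s.value for s in WeightStatus}
        assert set(df["Weight_status"].dropna()) <= allowed
        # written values match the in-memory results at written precision
        for res, (_, row) in zip(results, df.iterrows()):
            assert row["BMI_kgm2"] == pytest.approx(round(res.bmi_kgm2, 2))
            assert row["BMI_z"] == pytest.approx(round(res.bmi_z, 4))

    def test_empty_results_header_only(self, tmp_path):
        out = cohort.write_results([], tmp_path / "BMI_Results.csv")
        df = pd.read_csv(out)
        assert len(df) == 0 and "Weight_status" in df.columns
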