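import math

import pytest
from hypothesis import given, settings, strategies as st

from crossmeta.data_model import (
    ArmData,
    Dataset,
    DegenerateStudyError,
    StudyRecord,
    StudyType,
    ValidationError,
    arm_difference,
    read_dataset,
    to_normal_summary,
    write_dataset,
)
from conftest import make_study


class TestCSVRoundTrip:
    def test_read_shapes_and_missing(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text(
            "study_id,study_type,r_T,n_T,r_C,n_C,age_T,age_C\n"
            "a,randomised,5,100,10,100,71.2,68.8\n"
            "b,non_randomised,3,50,4,60,,70.0\n"
        )
        data = read_dataset(path)
        assert data.n_studies == 2
        assert data.covariate_names == ["age"]
        assert data.studies[0].study_type is StudyType.RANDOMISED
        assert data.studies[1].treatment_arm.covariates["age"] is None
        assert data.studies[1].control_arm.covariates["age"] == 70.0

    def test_empty_file_with_header_gives_empty_dataset(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("study_id,study_type,r_T,n_T,r_C,n_C\n")
        data = read_dataset(path)
        assert data.n_studies == 0 and data.covariate_names == []

    def test_invalid_counts_name_the_study(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text(
            "study_id,study_type,r_T,n_T,r_C,n_C\nbad,randomised,12,10,1,10\n"
        )
        with pytest.raises(ValidationError, match="bad"):
            read_dataset(path)

    def test_unknown_study_type_lists_accepted_labels(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("study_id,study_type,r_T,n_T,r_C,n_C\nx,observational,1,10,1,10\n")
        with pytest.raises(ValidationError, match="randomised"):
            read_dataset(path)

    def test_round_trip_preserves_cells(self, tiny_dataset, tmp_path):
        path = tmp_path / "rt.csv"
        write_dataset(tiny_dataset, path)
        back = read_dataset(path)
        for orig, new in zip(tiny_dataset.studies, back.studies):
            assert orig.study_id == new.study_id
            assert orig.treatment_arm.events == new.treatment_arm.events
            assert orig.control_arm.total == new.control_arm.total
            assert orig.treatment_arm.covariates == new.treatment_arm.covariates


class TestNormalSummary:
    def test_woolf_hand_value(self):
        # ln[(5/95)/(10/90)] and 1/5 + 1/95 + 1/10 + 1/90
        s = to_normal_summary(make_study(r_t=5, n_t=100, r_c=10, n_c=100))
        assert s.log_effect == pytest.approx(-0.74721, abs=1e-4)
        assert s.variance == pytest.approx(0.321637, abs=1e-5)

    def test_equal_risks_give_zero_log_or(self):
        s = to_normal_summary(make_study(r_t=20, n_t=100, r_c=20, n_c=100))
        assert s.log_effect == 0.0

    def test_zero_cell_continuity_correction(self):
        # all four cells get +0.5 before the formulas
        s = to_normal_summary(make_study(r_t=0, n_t=50, r_c=5, n_c=50), correction=0.5)
        a, b, c, d = 0.5, 50.5, 5.5, 45.5
        assert s.log_effect == pytest.approx(math.log((a / b) / (c / d)))
        assert s.variance == pytest.approx(1 / a + 1 / b + 1 / c + 1 / d)

    def test_double_zero_table_is_degenerate(self):
        with pytest.raises(DegenerateStudyError):
            to_normal_summary(make_study(r_t=0, n_t=50, r_c=0, n_c=50))

    @given(
        r_t=st.integers(1, 49),
        r_c=st.integers(1, 49),
        n_t=st.integers(50, 200),
        n_c=st.integers(50, 200),
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_under_arm_swap(self, r_t, r_c, n_t, n_c):
        study = make_study(r_t=r_t, n_t=n_t, r_c=r_c, n_c=n_c)
        swapped = StudyRecord(
            study_id=study.study_id,
            study_type=study.study_type,
            treatment_arm=study.control_arm,
            control_arm=study.treatment_arm,
        )
        a, b = to_normal_summary(study), to_normal_summary(swapped)
        assert a.log_effect == pytest.approx(-b.log_effect)
        assert a.variance == pytest.approx(b.variance)


class TestArmDifference:
    def test_difference_and_antisymmetry(self):
        study = make_study(cov_t={"age": 71.2}, cov_c={"age": 68.8})
        assert arm_difference(study, "age") == pytest.approx(2.4)
        swapped = StudyRecord(
            study_id="s",
            study_type=study.study_type,
            treatment_arm=study.control_arm,
            control_arm=study.treatment_arm,
        )
        assert arm_difference(swapped, "age") == pytest.approx(-2.4)

    def test_identical_arms_give_zero(self):
        study = make_study(cov_t={"age": 70.0}, cov_c={"age": 70.0})
        assert arm_difference(study, "age") == 0.0

    def test_missing_side_propagates_none(self):
        study = make_study(cov_t={"age": 70.0}, cov_c={"age": None})
        assert arm_difference(study, "age") is None

    def test_undeclared_covariate_errors(self):
        study = make_study(cov_t={"age": 70.0}, cov_c={"age": 70.0})
        with pytest.raises(ValidationError):
            arm_difference(study, "bmi")


class TestValidation:
    def test_proportion_covariate_outside_unit_interval(self):
        study = make_study(cov_t={"male": 1.2}, cov_c={"male": 0.9})
        with pytest.raises(ValidationError):
            study.validate()

    def test_mismatched_covariate_sets(self):
        study = make_study(cov_t={"age": 70.0}, cov_c={})
        with pytest.raises(ValidationError):
            study.validate()

    def test_three_level_needs_both_types(self):
        data = Dataset([make_study()], [])
        with pytest.raises(ValidationError):
            data.validate(require_both_types=True)
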