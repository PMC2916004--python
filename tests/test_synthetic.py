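import dataclasses
import math

import numpy as np
import pytest

from crossmeta.data_model import StudyType, arm_difference
from crossmeta.synthetic import (
    CovariateSim,
    SimConfig,
    base_case_config,
    generate,
    generate_confounded,
    imputed_case_config,
)


def zero_imbalance_config(seed=0, **overrides):
    """Base-case configuration with all arm differences forced to zero."""
    config = base_case_config(seed=seed, **overrides)
    covs = tuple(
        dataclasses.replace(c, imbalance_mean=(0.0, 0.0), imbalance_sd=(0.0, 0.0))
        for c in config.covariates
    )
    return dataclasses.replace(config, covariates=covs)


class TestGenerate:
    def test_base_case_shape(self):
        data, truth = generate(base_case_config(seed=1))
        assert data.n_studies == 44
        assert len(data.by_type(StudyType.RANDOMISED)) == 4
        assert len(data.by_type(StudyType.NON_RANDOMISED)) == 40
        assert data.covariate_names == ["male", "age", "cardiac"]
        assert len(truth.psi) == 44

    def test_deterministic(self):
        a, ta = generate(base_case_config(seed=5))
        b, tb = generate(base_case_config(seed=5))
        assert ta.psi == tb.psi
        for s1, s2 in zip(a.studies, b.studies):
            assert s1.treatment_arm.events == s2.treatment_arm.events
            assert s1.treatment_arm.covariates == s2.treatment_arm.covariates

    def test_counts_within_totals_and_proportions_bounded(self):
        data, _ = generate(imputed_case_config(seed=2, k_non_randomised=200))
        for s in data.studies:
            for arm in (s.treatment_arm, s.control_arm):
                assert 0 <= arm.events <= arm.total
                for name in ("male", "cardiac", "pulmonary", "renal"):
                    v = arm.covariates[name]
                    if v is not None:
                        assert 0.0 <= v <= 1.0

    def test_arm_difference_equals_drawn_difference(self):
        data, truth = generate(base_case_config(seed=3))
        for j, s in enumerate(data.studies):
            for m, name in enumerate(data.covariate_names):
                d = arm_difference(s, name)
                if d is not None:
                    assert d == pytest.approx(truth.differences[j][m], abs=1e-9)

    def test_imbalance_calibration_age(self):
        """Average age imbalance ~2.40 years (non-randomised) vs ~0.82 (randomised)."""
        config = base_case_config(seed=4, k_randomised=2000, k_non_randomised=2000)
        data, _ = generate(config)
        for stype, expected in ((StudyType.RANDOMISED, 0.82), (StudyType.NON_RANDOMISED, 2.40)):
            diffs = [arm_difference(s, "age") for s in data.by_type(stype)]
            assert np.mean(diffs) == pytest.approx(expected, abs=0.1)

    def test_missingness_fractions(self):
        config = imputed_case_config(seed=5, k_non_randomised=2000)
        data, _ = generate(config)
        nrs = data.by_type(StudyType.NON_RANDOMISED)
        for name, expected in (("pulmonary", 0.43), ("renal", 0.54)):
            share = np.mean([s.treatment_arm.covariates[name] is None for s in nrs])
            assert abs(share - expected) < 0.05

    def test_hierarchy_moments(self):
        """Spread of psi around its conditional mean matches sigma_i."""
        config = base_case_config(seed=6, k_randomised=1500, k_non_randomised=1500)
        data, truth = generate(config)
        alpha = np.array(truth.alpha)
        resid = {0: [], 1: []}
        for j, s in enumerate(data.studies):
            i = 0 if s.study_type is StudyType.RANDOMISED else 1
            mean = truth.theta[i] + float(alpha @ np.array(truth.differences[j]))
            resid[i].append(truth.psi[j] - mean)
        for i in (0, 1):
            observed = np.std(resid[i], ddof=1)
            se = truth.sigma[i] / math.sqrt(2 * (len(resid[i]) - 1))
            assert abs(observed - truth.sigma[i]) < 4 * se

    def test_zero_alpha_zero_imbalance_degenerates_to_unadjusted(self):
        config = zero_imbalance_config(seed=7, alpha_true=(0.0, 0.0, 0.0))
        data, truth = generate(config)
        for j, s in enumerate(data.studies):
            assert truth.differences[j] == [0.0, 0.0, 0.0]
            for name in data.covariate_names:
                assert arm_difference(s, name) == 0.0


class TestGenerateConfounded:
    def test_zero_strength_identical_to_generate(self):
        config = base_case_config(seed=8)
        a, ta = generate(config)
        b, tb = generate_confounded(config, 0.0)
        assert ta.psi == tb.psi and tb.induced_bias == 0.0
        for s1, s2 in zip(a.studies, b.studies):
            assert s1.treatment_arm.covariates == s2.treatment_arm.covariates

    def test_induced_bias_matches_analytic_shift(self):
        config = base_case_config(seed=9, k_non_randomised=4000)
        strength = 1.0
        data, truth = generate_confounded(config, strength)
        expected_bias = sum(
            a * strength * c.imbalance_mean[1]
            for a, c in zip(config.alpha_true, config.covariates)
        )
        assert truth.induced_bias == pytest.approx(expected_bias)
        # realised mean imbalance among non-randomised studies reflects the shift
        nrs = data.by_type(StudyType.NON_RANDOMISED)
        mean_age_diff = np.mean([arm_difference(s, "age") for s in nrs])
        assert mean_age_diff == pytest.approx(2.40 * (1 + strength), abs=0.15)

    def test_sign_flip_flips_bias_direction(self):
        config = base_case_config(seed=10)
        _, pos = generate_confounded(config, 1.0)
        _, neg = generate_confounded(config, -1.0)
        assert pos.induced_bias > 0 > neg.induced_bias
        assert pos.induced_bias == pytest.approx(-neg.induced_bias)


class TestConfigValidation:
    def test_alpha_length_mismatch(self):
        with pytest.raises(ValueError):
            SimConfig(alpha_true=(0.1,), covariates=())

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            base_case_config(k_randomised=-1)

    def test_truth_round_trip(self, tmp_path):
        _, truth = generate(base_case_config(seed=11))
        path = tmp_path / "truth.json"
        truth.to_json(path)
        from crossmeta.synthetic import TruthRecord

        back = TruthRecord.from_json(path)
        assert back == truth
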