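import math

import numpy as np
import pytest

from crossmeta.data_model import Dataset, StudyType
from crossmeta.models import (
    Adjustment,
    Downweighting,
    Likelihood,
    ModelSpec,
    ParameterState,
    PreparedModel,
    constraint_satisfied,
    log_likelihood,
    log_posterior,
    log_prior,
    psi_prior_mean,
)
from crossmeta.priors import base_case_priors
from conftest import make_study


def make_state(model: PreparedModel, **overrides) -> ParameterState:
    state = model.initial_state()
    for key, value in overrides.items():
        setattr(state, key, value)
    return state


class TestModelSpecInvariants:
    def test_arm_difference_requires_binomial(self):
        with pytest.raises(ValueError):
            ModelSpec(
                likelihood=Likelihood.NORMAL_THREE_LEVEL,
                adjustment=Adjustment.ARM_DIFFERENCE,
                covariates=("age",),
            )

    def test_constraint_requires_three_level(self):
        with pytest.raises(ValueError):
            ModelSpec(
                likelihood=Likelihood.NORMAL_TWO_LEVEL,
                downweighting=Downweighting.PREVOST_CONSTRAINT,
            )

    def test_adjustment_needs_covariates(self):
        with pytest.raises(ValueError):
            ModelSpec(adjustment=Adjustment.ARM_DIFFERENCE, covariates=())


class TestLogLikelihood:
    def test_binomial_hand_value(self):
        # one study, gamma=0, psi=0: both arms Binomial(10, 1/2) with 5 events
        data = Dataset([make_study(r_t=5, n_t=10, r_c=5, n_c=10)], [])
        spec = ModelSpec()
        model = PreparedModel(data, spec)
        state = make_state(model, psi=np.zeros(1), gamma=np.zeros(1))
        expected = 2 * math.log(math.comb(10, 5)) + 20 * math.log(0.5)
        assert model.log_likelihood(state) == pytest.approx(expected)

    def test_normal_zero_residuals(self, tiny_dataset):
        spec = ModelSpec(likelihood=Likelihood.NORMAL_THREE_LEVEL)
        model = PreparedModel(tiny_dataset, spec)
        state = make_state(model, psi=model.y.copy())
        expected = float(np.sum(-0.5 * np.log(2 * math.pi * model.s2)))
        assert model.log_likelihood(state) == pytest.approx(expected)

    def test_empty_dataset_contributes_zero(self):
        data = Dataset([], [])
        model = PreparedModel(data, ModelSpec())
        assert model.log_likelihood(model.initial_state()) == 0.0


class TestPsiPriorMean:
    def test_balanced_arms_reduce_to_theta(self):
        study = make_study(cov_t={"age": 70.0}, cov_c={"age": 70.0})
        spec = ModelSpec(adjustment=Adjustment.ARM_DIFFERENCE, covariates=("age",))
        state = ParameterState(
            mu=0.0,
            tau=0.2,
            theta=np.array([-0.7, -0.5]),
            sigma=np.array([0.2, 0.3]),
            psi=np.zeros(1),
            gamma=np.zeros(1),
            alpha=np.array([0.02]),
            beta=np.zeros(0),
        )
        assert psi_prior_mean(state, study, spec) == pytest.approx(-0.7)

    def test_arm_difference_hand_value(self):
        study = make_study(cov_t={"age": 71.2}, cov_c={"age": 68.8})
        spec = ModelSpec(adjustment=Adjustment.ARM_DIFFERENCE, covariates=("age",))
        state = ParameterState(
            mu=0.0,
            tau=0.2,
            theta=np.array([-0.7, -0.5]),
            sigma=np.array([0.2, 0.3]),
            psi=np.zeros(1),
            gamma=np.zeros(1),
            alpha=np.array([0.02]),
            beta=np.zeros(0),
        )
        # theta_1 + 0.02 * 2.4
        assert psi_prior_mean(state, study, spec) == pytest.approx(-0.652)

    def test_aggregate_at_grand_mean_reduces_to_theta(self):
        study = make_study(
            study_type=StudyType.NON_RANDOMISED,
            cov_t={"age": 70.0},
            cov_c={"age": 70.0},
        )
        spec = ModelSpec(adjustment=Adjustment.AGGREGATE, covariates=("age",))
        state = ParameterState(
            mu=0.0,
            tau=0.2,
            theta=np.array([-0.7, -0.5]),
            sigma=np.array([0.2, 0.3]),
            psi=np.zeros(1),
            gamma=np.zeros(1),
            alpha=np.zeros(0),
            beta=np.array([0.5]),
        )
        assert psi_prior_mean(state, study, spec, {"age": 70.0}) == pytest.approx(-0.5)

    def test_missing_covariate_identifies_study(self):
        study = make_study(study_id="gap", cov_t={"age": None}, cov_c={"age": 70.0})
        spec = ModelSpec(adjustment=Adjustment.ARM_DIFFERENCE, covariates=("age",))
        state = ParameterState(
            mu=0.0,
            tau=0.2,
            theta=np.zeros(2),
            sigma=np.ones(2),
            psi=np.zeros(1),
            gamma=np.zeros(1),
            alpha=np.zeros(1),
            beta=np.zeros(0),
        )
        with pytest.raises(ValueError, match="gap"):
            psi_prior_mean(state, study, spec)


class TestConstraint:
    @pytest.mark.parametrize(
        "mu,t1,t2,expected",
        [
            (0.0, 0.1, -0.2, True),
            (0.0, 0.3, -0.3, False),  # strict: a tie is violated
            (0.0, 0.5, 0.1, False),
        ],
    )
    def test_cases(self, mu, t1, t2, expected):
        assert constraint_satisfied(mu, t1, t2) is expected

    def test_reflection_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            mu, t1, t2 = rng.normal(size=3)
            assert constraint_satisfied(mu, t1, t2) == constraint_satisfied(-mu, -t1, -t2)


class TestLogPrior:
    def test_nonpositive_tau_is_minus_inf(self, tiny_dataset):
        spec = ModelSpec()
        model = PreparedModel(tiny_dataset, spec)
        state = make_state(model, tau=-0.5)
        assert model.log_prior(state) == -math.inf

    def test_constraint_indicator(self, tiny_dataset):
        spec = ModelSpec(downweighting=Downweighting.PREVOST_CONSTRAINT)
        model = PreparedModel(tiny_dataset, spec)
        bad = make_state(model, mu=0.0, theta=np.array([0.5, 0.1]))
        good = make_state(model, mu=0.0, theta=np.array([0.1, -0.2]))
        assert model.log_prior(bad) == -math.inf
        assert math.isfinite(model.log_prior(good))


class TestLogPosterior:
    def test_minus_inf_prior_propagates(self, tiny_dataset):
        spec = ModelSpec()
        state = make_state(PreparedModel(tiny_dataset, spec), tau=-1.0)
        assert log_posterior(state, tiny_dataset, spec) == -math.inf

    def test_empty_dataset_recovers_prior(self):
        data = Dataset([], [])
        spec = ModelSpec()
        model = PreparedModel(data, spec)
        state = model.initial_state()
        assert log_posterior(state, data, spec) == pytest.approx(
            log_prior(state, data, spec)
        )

    def test_finite_for_prior_draw(self, tiny_dataset):
        rng = np.random.default_rng(5)
        priors = base_case_priors()
        spec = ModelSpec(adjustment=Adjustment.ARM_DIFFERENCE, covariates=("age",))
        model = PreparedModel(tiny_dataset, spec)
        k = model.k
        state = ParameterState(
            mu=float(priors.mu.sample(rng)),
            tau=float(priors.tau.sample(rng)),
            theta=np.array([0.0, 0.0]),
            sigma=np.array(
                [priors.sigma_randomised.sample(rng), priors.sigma_non_randomised.sample(rng)]
            ),
            psi=rng.normal(0, 1, size=k),
            gamma=rng.normal(0, 1, size=k),
            alpha=rng.normal(0, 1, size=1),
            beta=np.zeros(0),
        )
        total = log_posterior(state, tiny_dataset, spec)
        assert math.isfinite(total)
        assert total == pytest.approx(
            log_likelihood(state, tiny_dataset, spec) + log_prior(state, tiny_dataset, spec)
        )

    def test_sum_decomposition(self, tiny_dataset):
        spec = ModelSpec()
        model = PreparedModel(tiny_dataset, spec)
        state = model.initial_state()
        assert log_posterior(state, tiny_dataset, spec) == pytest.approx(
            model.log_likelihood(state) + model.log_prior(state)
        )


class TestAdjustedStudySelection:
    def test_studies_missing_covariates_are_excluded(self):
        complete = make_study("ok", cov_t={"age": 71.0}, cov_c={"age": 69.0})
        gappy = make_study(
            "gap", StudyType.NON_RANDOMISED, cov_t={"age": None}, cov_c={"age": 70.0}
        )
        data = Dataset([complete, gappy], ["age"])
        spec = ModelSpec(adjustment=Adjustment.ARM_DIFFERENCE, covariates=("age",))
        model = PreparedModel(data, spec)
        assert model.k == 1
        assert model.studies[0].study_id == "ok"

    def test_sutton_mode_keeps_only_randomised(self, tiny_dataset):
        spec = ModelSpec(downweighting=Downweighting.SUTTON_PRIOR)
        model = PreparedModel(tiny_dataset, spec)
        assert all(s.study_type is StudyType.RANDOMISED for s in model.studies)
        assert not spec.three_level
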