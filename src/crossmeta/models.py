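"""Log-density assembly for the cross-design hierarchical models.

Variants
--------
* ``normal_two_level`` — classical random-effects meta-analysis on log-OR
  summaries: y_j ~ N(psi_j, s_j^2), psi_j ~ N(mu, sigma^2).
* ``normal_three_level`` — adds a study-type level: psi_ij ~ N(theta_i,
  sigma_i^2), theta_i ~ N(mu, tau^2), with i indexing randomised vs
  non-randomised studies.
* ``binomial_three_level`` — models the arm counts directly:
  r_C ~ Bin(n_C, expit(gamma)), r_T ~ Bin(n_T, expit(gamma + psi)), so psi is
  the study log odds ratio, with the same hierarchy above it.

Adjustments
-----------
* ``arm_difference`` — the bias-adjustment model: the prior mean of each
  study's log OR is theta_i + sum_m alpha_m (x_mT - x_mC), shifting the
  expected effect in proportion to the study's between-arm covariate
  imbalance.  Requires the binomial likelihood (arm-level data).
* ``aggregate`` — meta-regression on whole-study covariate values, centred at
  their across-study means; cannot correct within-study arm imbalance.

Downweighting
-------------
* ``prevost_constraint`` — joint prior indicator |mu - theta_1| < |mu -
  theta_2| asserting the randomised type-level effect sits closer to the
  population effect.
* ``sutton_prior`` — likelihood restricted to the randomised studies combined
  with an informative Normal prior on mu built from the pooled non-randomised
  estimate (see :func:`crossmeta.priors.build_informative_mu_prior`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
from scipy.special import gammaln

from .data_model import Dataset, StudyRecord, StudyType, arm_difference, pooled_covariate
from .priors import PriorSet

__all__ = [
    "Likelihood",
    "Adjustment",
    "Downweighting",
    "ModelSpec",
    "ParameterState",
    "PreparedModel",
    "constraint_satisfied",
    "psi_prior_mean",
    "log_likelihood",
    "log_prior",
    "log_posterior",
]

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)


class Likelihood(str, Enum):
    NORMAL_TWO_LEVEL = "normal_two_level"
    NORMAL_THREE_LEVEL = "normal_three_level"
    BINOMIAL_THREE_LEVEL = "binomial_three_level"


class Adjustment(str, Enum):
    NONE = "none"
    AGGREGATE = "aggregate"
    ARM_DIFFERENCE = "arm_difference"


class Downweighting(str, Enum):
    NONE = "none"
    PREVOST_CONSTRAINT = "prevost_constraint"
    SUTTON_PRIOR = "sutton_prior"


@dataclass(frozen=True)
class ModelSpec:
    """Which model variant to fit, with its priors and adjustment covariates.

    ``include_randomised_differences`` controls whether the (small) arm
    imbalances of randomised studies also enter the bias-adjustment term;
    by default they do, so all studies inform the bias coefficients.
    ``fixed`` holds named scalar parameters (e.g. ``{"sigma_1": 0.3}``) at a
    constant value during sampling — used for oracle checks and for fits with
    known variances.
    """

    likelihood: Likelihood = Likelihood.BINOMIAL_THREE_LEVEL
    adjustment: Adjustment = Adjustment.NONE
    downweighting: Downweighting = Downweighting.NONE
    priors: PriorSet = None  # type: ignore[assignment]
    covariates: tuple[str, ...] = ()
    include_randomised_differences: bool = True
    fixed: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.priors is None:
            from .priors import base_case_priors

            object.__setattr__(self, "priors", base_case_priors())
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if self.adjustment is Adjustment.ARM_DIFFERENCE and (
            self.likelihood is not Likelihood.BINOMIAL_THREE_LEVEL
        ):
            raise ValueError(
                "arm_difference adjustment is defined on the binomial arm-level model"
            )
        if self.adjustment is not Adjustment.NONE and not self.covariates:
            raise ValueError("an adjusted model needs at least one covariate")
        if self.downweighting is Downweighting.PREVOST_CONSTRAINT and (
            self.likelihood is Likelihood.NORMAL_TWO_LEVEL
        ):
            raise ValueError("the prior constraint needs a three-level likelihood")

    @property
    def three_level(self) -> bool:
        # The informative-prior downweighting collapses the hierarchy to a
        # two-level model over the randomised studies alone.
        if self.downweighting is Downweighting.SUTTON_PRIOR:
            return False
        return self.likelihood is not Likelihood.NORMAL_TWO_LEVEL

    @property
    def binomial(self) -> bool:
        return self.likelihood is Likelihood.BINOMIAL_THREE_LEVEL


@dataclass
class ParameterState:
    """One point in parameter space.

    Unused blocks (e.g. ``theta`` for a two-level model, ``gamma`` for a
    normal likelihood) are empty arrays.
    """

    mu: float
    tau: float
    theta: np.ndarray
    sigma: np.ndarray
    psi: np.ndarray
    gamma: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray

    def copy(self) -> "ParameterState":
        return ParameterState(
            mu=self.mu,
            tau=self.tau,
            theta=self.theta.copy(),
            sigma=self.sigma.copy(),
            psi=self.psi.copy(),
            gamma=self.gamma.copy(),
            alpha=self.alpha.copy(),
            beta=self.beta.copy(),
        )


def constraint_satisfied(mu: float, theta1: float, theta2: float) -> bool:
    """Strict version of the randomised-closer-to-mu prior constraint."""
    return abs(mu - theta1) < abs(mu - theta2)


# ---------------------------------------------------------------------------
# Prepared (vectorised) model
# ---------------------------------------------------------------------------


class PreparedModel:
    """A dataset/spec pair compiled to flat arrays for fast density evaluation.

    Adjusted fits drop studies missing a required covariate (logged); the
    informative-prior downweighting restricts to randomised studies.
    """

    def __init__(self, data: Dataset, spec: ModelSpec):
        self.spec = spec
        studies = list(data.studies)
        if spec.downweighting is Downweighting.SUTTON_PRIOR:
            studies = [s for s in studies if s.study_type is StudyType.RANDOMISED]
        if spec.adjustment is not Adjustment.NONE:
            kept = []
            for s in studies:
                missing = [c for c in spec.covariates if arm_difference(s, c) is None]
                if missing:
                    logger.warning(
                        "excluding study %s from adjusted fit: missing covariates %s",
                        s.study_id,
                        missing,
                    )
                else:
                    kept.append(s)
            studies = kept
        self.studies = studies
        self.k = len(studies)
        self.type_idx = np.array(
            [0 if s.study_type is StudyType.RANDOMISED else 1 for s in studies], dtype=int
        )
        self.r_t = np.array([s.treatment_arm.events for s in studies], dtype=float)
        self.n_t = np.array([s.treatment_arm.total for s in studies], dtype=float)
        self.r_c = np.array([s.control_arm.events for s in studies], dtype=float)
        self.n_c = np.array([s.control_arm.total for s in studies], dtype=float)

        if spec.binomial:
            self._choose = float(
                np.sum(gammaln(self.n_t + 1) - gammaln(self.r_t + 1) - gammaln(self.n_t - self.r_t + 1))
                + np.sum(gammaln(self.n_c + 1) - gammaln(self.r_c + 1) - gammaln(self.n_c - self.r_c + 1))
            )
            self.y = self.s2 = None
        else:
            from .data_model import to_normal_summary

            summaries = [to_normal_summary(s) for s in studies]
            self.y = np.array([m.log_effect for m in summaries])
            self.s2 = np.array([m.variance for m in summaries])
            self._choose = 0.0

        M = len(spec.covariates)
        self.M = M
        if spec.adjustment is Adjustment.ARM_DIFFERENCE:
            diffs = np.zeros((self.k, M))
            for j, s in enumerate(studies):
                for m, name in enumerate(spec.covariates):
                    diffs[j, m] = arm_difference(s, name)
            if not spec.include_randomised_differences:
                diffs[self.type_idx == 0, :] = 0.0
            self.design = diffs
        elif spec.adjustment is Adjustment.AGGREGATE:
            agg = np.zeros((self.k, M))
            for j, s in enumerate(studies):
                for m, name in enumerate(spec.covariates):
                    agg[j, m] = pooled_covariate(s, name)
            self.aggregate_means = agg.mean(axis=0) if self.k else np.zeros(M)
            self.design = agg - self.aggregate_means
        else:
            self.design = np.zeros((self.k, 0))

    # -- state plumbing -------------------------------------------------

    def initial_state(self, rng: np.random.Generator | None = None) -> ParameterState:
        """A moderate starting point with finite log-posterior."""
        spec = self.spec
        rng = rng or np.random.default_rng(0)
        k, M = self.k, self.M
        if spec.binomial:
            p_c = (self.r_c + 0.5) / (self.n_c + 1.0)
            p_t = (self.r_t + 0.5) / (self.n_t + 1.0)
            gamma = np.log(p_c / (1 - p_c))
            psi = np.log(p_t / (1 - p_t)) - gamma
        else:
            gamma = np.zeros(0)
            psi = self.y.copy() if k else np.zeros(0)
        mu = float(np.mean(psi)) if k else 0.0
        theta = np.full(2, mu) if spec.three_level else np.zeros(0)
        if spec.downweighting is Downweighting.PREVOST_CONSTRAINT:
            theta = np.array([mu, mu + 0.05])  # strict constraint holds at start
        state = ParameterState(
            mu=mu,
            tau=0.2 if spec.three_level else 0.0,
            theta=theta,
            sigma=np.full(2 if spec.three_level else 1, 0.3),
            psi=psi,
            gamma=gamma,
            alpha=np.zeros(M if spec.adjustment is Adjustment.ARM_DIFFERENCE else 0),
            beta=np.zeros(M if spec.adjustment is Adjustment.AGGREGATE else 0),
        )
        self.apply_fixed(state)
        return state

    def apply_fixed(self, state: ParameterState) -> None:
        for name, value in self.spec.fixed.items():
            self.set_param(state, name, float(value))

    def set_param(self, state: ParameterState, name: str, value: float) -> None:
        if name == "mu":
            state.mu = value
        elif name == "tau":
            state.tau = value
        elif name.startswith("theta_"):
            state.theta[int(name.split("_")[1]) - 1] = value
        elif name.startswith("sigma_"):
            state.sigma[int(name.split("_")[1]) - 1] = value
        elif name.startswith("psi_"):
            state.psi[int(name.split("_")[1])] = value
        elif name.startswith("gamma_"):
            state.gamma[int(name.split("_")[1])] = value
        elif name.startswith("alpha_"):
            state.alpha[list(self.spec.covariates).index(name[6:])] = value
        elif name.startswith("beta_"):
            state.beta[list(self.spec.covariates).index(name[5:])] = value
        else:
            raise KeyError(f"unknown parameter {name!r}")

    def param_names(self) -> list[str]:
        spec = self.spec
        names = ["mu"]
        if spec.three_level:
            names += ["theta_1", "theta_2", "tau", "sigma_1", "sigma_2"]
        else:
            names += ["sigma_1"]
        names += [f"psi_{j}" for j in range(self.k)]
        if spec.binomial:
            names += [f"gamma_{j}" for j in range(self.k)]
        if spec.adjustment is Adjustment.ARM_DIFFERENCE:
            names += [f"alpha_{c}" for c in spec.covariates]
        if spec.adjustment is Adjustment.AGGREGATE:
            names += [f"beta_{c}" for c in spec.covariates]
        return names

    def flatten(self, state: ParameterState) -> np.ndarray:
        parts = [np.atleast_1d(state.mu)]
        if self.spec.three_level:
            parts += [state.theta, np.atleast_1d(state.tau), state.sigma]
        else:
            parts += [state.sigma]
        parts.append(state.psi)
        if self.spec.binomial:
            parts.append(state.gamma)
        if state.alpha.size:
            parts.append(state.alpha)
        if state.beta.size:
            parts.append(state.beta)
        return np.concatenate(parts) if parts else np.zeros(0)

    # -- densities ------------------------------------------------------

    def psi_means(self, state: ParameterState) -> np.ndarray:
        """Prior mean of each study's underlying log OR under the adjustment."""
        if self.spec.three_level:
            base = state.theta[self.type_idx] if self.k else np.zeros(0)
        else:
            base = np.full(self.k, state.mu)
        if self.spec.adjustment is Adjustment.ARM_DIFFERENCE:
            return base + self.design @ state.alpha
        if self.spec.adjustment is Adjustment.AGGREGATE:
            return base + self.design @ state.beta
        return base

    def psi_sds(self, state: ParameterState) -> np.ndarray:
        if self.spec.three_level:
            return state.sigma[self.type_idx]
        return np.full(self.k, state.sigma[0])

    def loglik_treatment(self, psi: np.ndarray, gamma: np.ndarray) -> np.ndarray:
        eta = gamma + psi
        return self.r_t * eta - self.n_t * np.logaddexp(0.0, eta)

    def loglik_control(self, gamma: np.ndarray) -> np.ndarray:
        return self.r_c * gamma - self.n_c * np.logaddexp(0.0, gamma)

    def log_likelihood(self, state: ParameterState) -> float:
        if self.k == 0:
            return 0.0
        if self.spec.binomial:
            return float(
                np.sum(self.loglik_treatment(state.psi, state.gamma))
                + np.sum(self.loglik_control(state.gamma))
                + self._choose
            )
        resid = self.y - state.psi
        return float(np.sum(-0.5 * (resid**2 / self.s2 + np.log(self.s2) + _LOG_2PI)))

    def log_prior(self, state: ParameterState) -> float:
        spec = self.spec
        priors = spec.priors
        if spec.three_level:
            if state.tau <= 0 or np.any(state.sigma <= 0):
                return -math.inf
            if spec.downweighting is Downweighting.PREVOST_CONSTRAINT and not (
                constraint_satisfied(state.mu, state.theta[0], state.theta[1])
            ):
                return -math.inf
            total = float(priors.mu.log_density(state.mu))
            total += float(priors.tau.log_density(state.tau))
            total += float(priors.sigma_randomised.log_density(state.sigma[0]))
            total += float(priors.sigma_non_randomised.log_density(state.sigma[1]))
            total += float(np.sum(_normal_logpdf(state.theta, state.mu, state.tau)))
        else:
            if np.any(state.sigma <= 0):
                return -math.inf
            total = float(priors.mu.log_density(state.mu))
            total += float(priors.sigma_randomised.log_density(state.sigma[0]))
        if not math.isfinite(total):
            return -math.inf
        if self.k:
            means = self.psi_means(state)
            sds = self.psi_sds(state)
            total += float(np.sum(_normal_logpdf(state.psi, means, sds)))
        if spec.binomial and self.k:
            total += float(np.sum(priors.gamma.log_density(state.gamma)))
        if state.alpha.size:
            total += float(np.sum(priors.alpha.log_density(state.alpha)))
        if state.beta.size:
            total += float(np.sum(priors.alpha.log_density(state.beta)))
        return total

    def log_posterior(self, state: ParameterState) -> float:
        lp = self.log_prior(state)
        if not math.isfinite(lp):
            return -math.inf
        return lp + self.log_likelihood(state)


def _normal_logpdf(x, mean, sd):
    return -0.5 * _LOG_2PI - np.log(sd) - 0.5 * ((x - mean) / sd) ** 2


# ---------------------------------------------------------------------------
# Public per-study / whole-model operations
# ---------------------------------------------------------------------------


def psi_prior_mean(
    state: ParameterState,
    study: StudyRecord,
    spec: ModelSpec,
    aggregate_centering: Mapping[str, float] | None = None,
) -> float:
    """Prior mean of one study's underlying log OR under the chosen adjustment.

    For the aggregate adjustment the study's pooled covariate values are
    centred by ``aggregate_centering`` (covariate name -> across-study mean;
    zeros if omitted).
    """
    i = 0 if study.study_type is StudyType.RANDOMISED else 1
    base = float(state.theta[i]) if state.theta.size else state.mu
    if spec.adjustment is Adjustment.NONE:
        return base
    if spec.adjustment is Adjustment.ARM_DIFFERENCE:
        if not spec.include_randomised_differences and i == 0:
            return base
        total = base
        for m, name in enumerate(spec.covariates):
            diff = arm_difference(study, name)
            if diff is None:
                raise ValueError(
                    f"study {study.study_id!r}: covariate {name!r} missing; "
                    "impute or exclude before an adjusted fit"
                )
            total += state.alpha[m] * diff
        return total
    total = base
    centering = aggregate_centering or {}
    for m, name in enumerate(spec.covariates):
        pooled = pooled_covariate(study, name)
        if pooled is None:
            raise ValueError(
                f"study {study.study_id!r}: covariate {name!r} missing; "
                "impute or exclude before an adjusted fit"
            )
        total += state.beta[m] * (pooled - centering.get(name, 0.0))
    return total


def log_likelihood(state: ParameterState, data: Dataset, spec: ModelSpec) -> float:
    """Total log likelihood of the data under ``state`` (constants included)."""
    return PreparedModel(data, spec).log_likelihood(state)


def log_prior(state: ParameterState, data: Dataset, spec: ModelSpec) -> float:
    """Hierarchical prior density (hyperpriors plus the psi and theta levels)."""
    return PreparedModel(data, spec).log_prior(state)


def log_posterior(state: ParameterState, data: Dataset, spec: ModelSpec) -> float:
    return PreparedModel(data, spec).log_posterior(state)
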