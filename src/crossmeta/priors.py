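"""Prior specifications for the hierarchical synthesis models.

Three named sets ship with the package:

* ``base_case_priors`` — "reasonably vague": half-normal(0.51) on the
  between-study and between-study-type standard deviations (the sd of an
  untruncated Normal with variance 0.26), Normal(0, 10) on the overall log
  odds ratio mu, and Normal(0, 1000) on the control-arm log odds and the
  bias coefficients.
* ``prevost_priors`` — "fairly unrestrictive": tighter half-normals,
  scale 0.36 for the within-type sds and 0.18 for the between-type sd.
* ``vaguest_priors`` — half-normal(1.0) for sigma_1 and tau, Uniform(0, 10)
  for the non-randomised between-study sd.

Half-normals are parameterised by the sd-scale of the underlying untruncated
normal; normals by (mean, sd).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "PriorFamily",
    "PriorSpec",
    "PriorSet",
    "base_case_priors",
    "prevost_priors",
    "vaguest_priors",
    "build_informative_mu_prior",
    "named_prior_set",
    "write_prior_config",
    "read_prior_config",
]

_LOG_2PI = math.log(2.0 * math.pi)


class PriorFamily(str, Enum):
    NORMAL = "normal"
    HALF_NORMAL = "half_normal"
    UNIFORM = "uniform"


@dataclass(frozen=True)
class PriorSpec:
    """One univariate prior: normal(mean, sd), half_normal(scale), uniform(lo, hi)."""

    family: PriorFamily
    param1: float
    param2: float

    def __post_init__(self):
        if self.family is PriorFamily.NORMAL and self.param2 <= 0:
            raise ValueError("normal sd must be positive")
        if self.family is PriorFamily.HALF_NORMAL and self.param2 <= 0:
            raise ValueError("half-normal scale must be positive")
        if self.family is PriorFamily.UNIFORM and not self.param1 < self.param2:
            raise ValueError("uniform needs lower < upper")

    # -- densities -----------------------------------------------------

    def log_density(self, x: float | np.ndarray) -> float | np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.family is PriorFamily.NORMAL:
            mean, sd = self.param1, self.param2
            out = -0.5 * _LOG_2PI - math.log(sd) - 0.5 * ((x - mean) / sd) ** 2
        elif self.family is PriorFamily.HALF_NORMAL:
            scale = self.param2
            out = np.where(
                x >= 0,
                math.log(2.0) - 0.5 * _LOG_2PI - math.log(scale) - 0.5 * (x / scale) ** 2,
                -np.inf,
            )
        else:
            lo, hi = self.param1, self.param2
            out = np.where((x >= lo) & (x <= hi), -math.log(hi - lo), -np.inf)
        return out if out.ndim else float(out)

    def sample(self, rng: np.random.Generator, size=None):
        if self.family is PriorFamily.NORMAL:
            return rng.normal(self.param1, self.param2, size=size)
        if self.family is PriorFamily.HALF_NORMAL:
            return np.abs(rng.normal(0.0, self.param2, size=size))
        return rng.uniform(self.param1, self.param2, size=size)

    def quantile(self, q):
        from scipy import stats

        if self.family is PriorFamily.NORMAL:
            return stats.norm.ppf(q, loc=self.param1, scale=self.param2)
        if self.family is PriorFamily.HALF_NORMAL:
            return stats.halfnorm.ppf(q, scale=self.param2)
        return stats.uniform.ppf(q, loc=self.param1, scale=self.param2 - self.param1)

    def cdf(self, x):
        from scipy import stats

        if self.family is PriorFamily.NORMAL:
            return stats.norm.cdf(x, loc=self.param1, scale=self.param2)
        if self.family is PriorFamily.HALF_NORMAL:
            return stats.halfnorm.cdf(x, scale=self.param2)
        return stats.uniform.cdf(x, loc=self.param1, scale=self.param2 - self.param1)

    @property
    def support(self) -> tuple[float, float]:
        if self.family is PriorFamily.NORMAL:
            return (-math.inf, math.inf)
        if self.family is PriorFamily.HALF_NORMAL:
            return (0.0, math.inf)
        return (self.param1, self.param2)


@dataclass(frozen=True)
class PriorSet:
    """The complete prior assignment for every unknown in a model fit."""

    mu: PriorSpec
    tau: PriorSpec
    sigma_randomised: PriorSpec
    sigma_non_randomised: PriorSpec
    gamma: PriorSpec
    alpha: PriorSpec
    label: str = "custom"

    def sigma(self, type_index: int) -> PriorSpec:
        """Prior for the between-study sd of study type 0 (RCT) or 1 (non-RCT)."""
        return self.sigma_randomised if type_index == 0 else self.sigma_non_randomised

    def with_mu(self, mu: PriorSpec) -> "PriorSet":
        return replace(self, mu=mu, label="custom")


_VAGUE_NORMAL = PriorSpec(PriorFamily.NORMAL, 0.0, math.sqrt(1000.0))


def base_case_priors() -> PriorSet:
    """The package's default, 'reasonably vague' prior set."""
    return PriorSet(
        mu=PriorSpec(PriorFamily.NORMAL, 0.0, math.sqrt(10.0)),
        tau=PriorSpec(PriorFamily.HALF_NORMAL, 0.0, 0.51),
        sigma_randomised=PriorSpec(PriorFamily.HALF_NORMAL, 0.0, 0.51),
        sigma_non_randomised=PriorSpec(PriorFamily.HALF_NORMAL, 0.0, 0.51),
        gamma=_VAGUE_NORMAL,
        alpha=_VAGUE_NORMAL,
        label="base_case",
    )


def prevost_priors() -> PriorSet:
    """'Fairly unrestrictive' variance priors; the rest as in the base case."""
    base = base_case_priors()
    return replace(
        base,
        tau=PriorSpec(PriorFamily.HALF_NORMAL, 0.0, 0.18),
        sigma_randomised=PriorSpec(PriorFamily.HALF_NORMAL, 0.0, 0.36),
        sigma_non_randomised=PriorSpec(PriorFamily.HALF_NORMAL, 0.0, 0.36),
        label="prevost",
    )


def vaguest_priors() -> PriorSet:
    """Least informative shipped set: wide half-normals and a Uniform(0,10) sigma_2."""
    base = base_case_priors()
    return replace(
        base,
        tau=PriorSpec(PriorFamily.HALF_NORMAL, 0.0, 1.0),
        sigma_randomised=PriorSpec(PriorFamily.HALF_NORMAL, 0.0, 1.0),
        sigma_non_randomised=PriorSpec(PriorFamily.UNIFORM, 0.0, 10.0),
        label="vaguest",
    )


_NAMED = {
    "base_case": base_case_priors,
    "prevost": prevost_priors,
    "vaguest": vaguest_priors,
}


def named_prior_set(name: str) -> PriorSet:
    try:
        return _NAMED[name]()
    except KeyError:
        raise ValueError(f"unknown prior set {name!r}; choose from {sorted(_NAMED)}") from None


def build_informative_mu_prior(
    pooled_log_or_nrs: float,
    pooled_variance_rct: float,
    inflation: float = 4.0,
) -> PriorSpec:
    """Informative prior on mu for the prior-based downweighting analysis.

    Centred on the pooled non-randomised log odds ratio with variance equal to
    ``inflation`` times the pooled variance of the randomised studies, so the
    non-randomised evidence enters only through a deliberately diffuse prior.
    """
    if not (math.isfinite(pooled_log_or_nrs) and math.isfinite(pooled_variance_rct)):
        raise ValueError("pooled inputs must be finite")
    variance = inflation * pooled_variance_rct
    if variance <= 0:
        raise ValueError("resulting prior variance must be positive")
    return PriorSpec(PriorFamily.NORMAL, pooled_log_or_nrs, math.sqrt(variance))


# ---------------------------------------------------------------------------
# Plain-text config round-trip (key = family param1 param2)
# ---------------------------------------------------------------------------

_FIELDS = ("mu", "tau", "sigma_randomised", "sigma_non_randomised", "gamma", "alpha")


def write_prior_config(priors: PriorSet, path: str | Path) -> None:
    lines = [f"label = {priors.label}"]
    for name in _FIELDS:
        spec: PriorSpec = getattr(priors, name)
        lines.append(f"{name} = {spec.family.value} {spec.param1!r} {spec.param2!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_prior_config(path: str | Path) -> PriorSet:
    fields: dict = {}
    label = "custom"
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key == "label":
            label = value
            continue
        if key not in _FIELDS:
            raise ValueError(f"unknown prior key {key!r}")
        parts = value.split()
        if len(parts) != 3:
            raise ValueError(f"prior line for {key!r} needs 'family param1 param2'")
        fields[key] = PriorSpec(PriorFamily(parts[0]), float(parts[1]), float(parts[2]))
    missing = [f for f in _FIELDS if f not in fields]
    if missing:
        raise ValueError(f"prior config missing entries: {missing}")
    return PriorSet(label=label, **fields)
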