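"""Adaptive random-walk Metropolis-within-Gibbs sampling and posterior summaries.

The sampler cycles through parameter blocks (study log odds ratios psi and
control log odds gamma as vector blocks with element-wise accept/reject —
valid because they are conditionally independent given the rest — and the
remaining parameters as scalar blocks).  Standard deviations (tau, sigma_i)
are updated on the log scale with the Jacobian correction.  Proposal scales
are tuned toward a target acceptance rate during burn-in only and frozen
afterwards, so the post-burn-in kernel leaves the posterior invariant.

Shipped defaults follow the production configuration of two chains with a
100 000-iteration burn-in and 100 000 retained iterations; tests and the
bundled simulation studies use much smaller, documented configurations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import Dataset
from .models import Downweighting, ModelSpec, PreparedModel
from .priors import PriorFamily, PriorSpec

#: lower bound for sd proposals; keeps tau/sigma away from numerical zero
_SD_FLOOR = 1e-8

__all__ = [
    "MCMCConfig",
    "PosteriorSamples",
    "Summary",
    "run_mcmc",
    "gelman_rubin",
    "effective_sample_size",
    "summarize",
]


@dataclass(frozen=True)
class MCMCConfig:
    burn_in: int = 100_000
    iterations: int = 100_000
    chains: int = 2
    thin: int = 1
    seed: int = 0
    adapt_interval: int = 50
    target_acceptance: float = 0.44

    def __post_init__(self):
        for name in ("burn_in", "iterations", "chains", "thin", "adapt_interval"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 < self.target_acceptance < 1.0:
            raise ValueError("target_acceptance must lie in (0, 1)")


@dataclass
class Summary:
    """Posterior median and equal-tailed 95% credible interval."""

    parameter: str
    median: float
    cri_low: float
    cri_high: float
    scale: str = "log_or"


@dataclass
class PosteriorSamples:
    """Post burn-in draws: array of shape (chains, n_draws, n_params)."""

    draws: np.ndarray
    param_names: list[str]
    acceptance_rates: dict[str, float]
    config: MCMCConfig
    spec: ModelSpec

    def get(self, parameter: str) -> np.ndarray:
        """Draws of one parameter, shape (chains, n_draws)."""
        try:
            idx = self.param_names.index(parameter)
        except ValueError:
            raise KeyError(
                f"unknown parameter {parameter!r}; available: {self.param_names}"
            ) from None
        return self.draws[:, :, idx]

    def pooled(self, parameter: str) -> np.ndarray:
        return self.get(parameter).reshape(-1)

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for c in range(self.draws.shape[0]):
            frame = pd.DataFrame(self.draws[c], columns=self.param_names)
            frame.insert(0, "chain", c)
            frames.append(frame)
        return pd.concat(frames, ignore_index=True)

    def export_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fast scalar log-densities for the hyperprior conditionals
# ---------------------------------------------------------------------------


def _scalar_logpdf(spec: PriorSpec):
    if spec.family is PriorFamily.NORMAL:
        mean, sd = spec.param1, spec.param2
        const = -math.log(sd)

        def f(x: float) -> float:
            z = (x - mean) / sd
            return const - 0.5 * z * z

    elif spec.family is PriorFamily.HALF_NORMAL:
        scale = spec.param2
        const = -math.log(scale)

        def f(x: float) -> float:
            if x < 0:
                return -math.inf
            z = x / scale
            return const - 0.5 * z * z

    else:
        lo, hi = spec.param1, spec.param2

        def f(x: float) -> float:
            return 0.0 if lo <= x <= hi else -math.inf

    return f


class _ChainSampler:
    """One chain of the Metropolis-within-Gibbs sweep over a prepared model."""

    def __init__(self, model: PreparedModel, config: MCMCConfig, rng: np.random.Generator):
        self.m = model
        self.spec = model.spec
        self.cfg = config
        self.rng = rng
        self.state = model.initial_state(rng)
        if not math.isfinite(model.log_posterior(self.state)):
            for _ in range(100):  # jitter until a finite starting point is found
                trial = model.initial_state(rng)
                trial.psi = trial.psi + rng.normal(0, 0.1, size=trial.psi.shape)
                model.apply_fixed(trial)
                if math.isfinite(model.log_posterior(trial)):
                    self.state = trial
                    break
            else:
                raise RuntimeError("could not construct a finite-log-posterior initial state")

        self.fixed = set(self.spec.fixed)
        k, M = model.k, model.M
        self.scale_psi = np.full(k, 0.5)
        self.scale_gamma = np.full(k, 0.5)
        self.scales = {
            "mu": 0.3,
            "tau": 0.5,
            "theta_1": 0.3,
            "theta_2": 0.3,
            "sigma_1": 0.5,
            "sigma_2": 0.5,
            "shift": 0.5,
        }
        names = (
            [f"alpha_{c}" for c in self.spec.covariates]
            if self.state.alpha.size
            else [f"beta_{c}" for c in self.spec.covariates] if self.state.beta.size else []
        )
        self.coef_names = names
        for n in names:
            self.scales[n] = 0.3
        self.acc: dict[str, float] = {}
        self.tries: dict[str, float] = {}
        self._adapt_round = 0

        p = self.spec.priors
        self.lp_mu = _scalar_logpdf(p.mu)
        self.lp_tau = _scalar_logpdf(p.tau)
        self.lp_sigma = (_scalar_logpdf(p.sigma_randomised), _scalar_logpdf(p.sigma_non_randomised))
        self.lp_coef = _scalar_logpdf(p.alpha)
        self.gamma_prior_mean = p.gamma.param1
        self.gamma_prior_sd = p.gamma.param2
        self.constrained = self.spec.downweighting is Downweighting.PREVOST_CONSTRAINT
        self.type_masks = [model.type_idx == 0, model.type_idx == 1]

    # -- bookkeeping ----------------------------------------------------

    def _record(self, name: str, accepted: float, tried: float = 1.0) -> None:
        self.acc[name] = self.acc.get(name, 0.0) + accepted
        self.tries[name] = self.tries.get(name, 0.0) + tried

    def adapt(self) -> None:
        self._adapt_round += 1
        step = min(0.5, self._adapt_round**-0.6) * 2.0
        target = self.cfg.target_acceptance
        for name, scale in self.scales.items():
            tried = self.tries.get(name, 0.0)
            if tried:
                rate = self.acc[name] / tried
                self.scales[name] = scale * math.exp(step * (rate - target))
        for vec_name, scales in (("psi", self.scale_psi), ("gamma", self.scale_gamma)):
            tried = self.tries.get(vec_name, 0.0)
            if tried:
                rates = self._vec_acc[vec_name] / tried
                scales *= np.exp(step * (rates - target))
        self.acc.clear()
        self.tries.clear()
        self._vec_acc = {
            "psi": np.zeros(self.m.k),
            "gamma": np.zeros(self.m.k),
        }

    # -- block updates ---------------------------------------------------

    def _update_psi(self) -> None:
        m, s = self.m, self.state
        k = m.k
        if k == 0 or "psi" in self.fixed:
            return
        prop = s.psi + self.scale_psi * self.rng.standard_normal(k)
        means = m.psi_means(s)
        sds = m.psi_sds(s)
        if self.spec.binomial:
            delta = m.loglik_treatment(prop, s.gamma) - m.loglik_treatment(s.psi, s.gamma)
        else:
            delta = -0.5 * ((m.y - prop) ** 2 - (m.y - s.psi) ** 2) / m.s2
        delta += -0.5 * ((prop - means) ** 2 - (s.psi - means) ** 2) / sds**2
        accept = np.log(self.rng.random(k)) < delta
        s.psi = np.where(accept, prop, s.psi)
        self._vec_acc["psi"] += accept

    def _update_gamma(self) -> None:
        m, s = self.m, self.state
        k = m.k
        if k == 0 or not self.spec.binomial or "gamma" in self.fixed:
            return
        prop = s.gamma + self.scale_gamma * self.rng.standard_normal(k)
        delta = (
            m.loglik_treatment(s.psi, prop)
            - m.loglik_treatment(s.psi, s.gamma)
            + m.loglik_control(prop)
            - m.loglik_control(s.gamma)
        )
        delta += -0.5 * (
            ((prop - self.gamma_prior_mean) ** 2 - (s.gamma - self.gamma_prior_mean) ** 2)
            / self.gamma_prior_sd**2
        )
        accept = np.log(self.rng.random(k)) < delta
        s.gamma = np.where(accept, prop, s.gamma)
        self._vec_acc["gamma"] += accept

    def _psi_resid_logp(self, means: np.ndarray, sds: np.ndarray) -> float:
        s = self.state
        if self.m.k == 0:
            return 0.0
        return float(np.sum(-np.log(sds) - 0.5 * ((s.psi - means) / sds) ** 2))

    def _update_theta(self, i: int) -> None:
        name = f"theta_{i + 1}"
        if name in self.fixed:
            return
        s = self.state
        mask = self.type_masks[i]
        cur = s.theta[i]
        prop = cur + self.scales[name] * self.rng.standard_normal()
        if self.constrained:
            t1, t2 = (prop, s.theta[1]) if i == 0 else (s.theta[0], prop)
            if not abs(s.mu - t1) < abs(s.mu - t2):
                self._record(name, 0.0)
                return
        sigma_i = s.sigma[i]
        adj = self._adjust_term()
        resid = s.psi[mask] - (adj[mask] if adj is not None else 0.0)
        delta = -0.5 * (np.sum((resid - prop) ** 2) - np.sum((resid - cur) ** 2)) / sigma_i**2
        delta += -0.5 * ((prop - s.mu) ** 2 - (cur - s.mu) ** 2) / s.tau**2
        if math.log(self.rng.random()) < delta:
            s.theta[i] = prop
            self._record(name, 1.0)
        else:
            self._record(name, 0.0)

    def _adjust_term(self):
        s = self.state
        if s.alpha.size:
            return self.m.design @ s.alpha
        if s.beta.size:
            return self.m.design @ s.beta
        return None

    def _update_mu(self) -> None:
        if "mu" in self.fixed:
            return
        s = self.state
        cur = s.mu
        prop = cur + self.scales["mu"] * self.rng.standard_normal()
        if self.constrained and not abs(prop - s.theta[0]) < abs(prop - s.theta[1]):
            self._record("mu", 0.0)
            return
        delta = self.lp_mu(prop) - self.lp_mu(cur)
        if self.spec.three_level:
            delta += -0.5 * float(
                np.sum((s.theta - prop) ** 2 - (s.theta - cur) ** 2)
            ) / s.tau**2
        elif self.m.k:
            adj = self._adjust_term()
            base = adj if adj is not None else 0.0
            resid = s.psi - base
            delta += (
                -0.5
                * float(np.sum((resid - prop) ** 2 - (resid - cur) ** 2))
                / s.sigma[0] ** 2
            )
        if math.log(self.rng.random()) < delta:
            s.mu = prop
            self._record("mu", 1.0)
        else:
            self._record("mu", 0.0)

    def _update_tau(self) -> None:
        if "tau" in self.fixed or not self.spec.three_level:
            return
        s = self.state
        cur = s.tau
        prop = cur * math.exp(self.scales["tau"] * self.rng.standard_normal())
        if prop < _SD_FLOOR:
            self._record("tau", 0.0)
            return

        # conditional: theta level + hyperprior; Jacobian from log-scale proposal
        def cond(tau: float) -> float:
            lp = self.lp_tau(tau)
            if not math.isfinite(lp):
                return -math.inf
            return lp + float(np.sum(-math.log(tau) - 0.5 * ((s.theta - s.mu) / tau) ** 2))

        delta = cond(prop) - cond(cur) + math.log(prop) - math.log(cur)
        if math.log(self.rng.random()) < delta:
            s.tau = prop
            self._record("tau", 1.0)
        else:
            self._record("tau", 0.0)

    def _update_sigma(self, i: int) -> None:
        name = f"sigma_{i + 1}"
        if name in self.fixed or i >= self.state.sigma.size:
            return
        s = self.state
        if self.spec.three_level:
            mask = self.type_masks[i]
            base = s.theta[i]
        else:
            mask = slice(None)
            base = s.mu
        adj = self._adjust_term()
        psi = s.psi[mask]
        means = base + (adj[mask] if adj is not None else 0.0)
        n = psi.size
        cur = s.sigma[i]
        prop = cur * math.exp(self.scales[name] * self.rng.standard_normal())
        if prop < _SD_FLOOR:
            self._record(name, 0.0)
            return
        lp = self.lp_sigma[i]

        def cond(sig: float) -> float:
            h = lp(sig)
            if not math.isfinite(h):
                return -math.inf
            if n == 0:
                return h
            return h - n * math.log(sig) - 0.5 * float(np.sum((psi - means) ** 2)) / sig**2

        delta = cond(prop) - cond(cur) + math.log(prop) - math.log(cur)
        if math.log(self.rng.random()) < delta:
            s.sigma[i] = prop
            self._record(name, 1.0)
        else:
            self._record(name, 0.0)

    def _update_coefficients(self) -> None:
        s = self.state
        coef = s.alpha if s.alpha.size else s.beta
        if coef.size == 0:
            return
        design = self.m.design
        sds = self.m.psi_sds(s)
        if self.spec.three_level:
            base = s.theta[self.m.type_idx]
        else:
            base = s.mu
        resid = s.psi - base - design @ coef
        for mdx, name in enumerate(self.coef_names):
            if name in self.fixed:
                continue
            step = self.scales[name] * self.rng.standard_normal()
            new_resid = resid - step * design[:, mdx]
            delta = -0.5 * float(np.sum((new_resid**2 - resid**2) / sds**2))
            delta += self.lp_coef(coef[mdx] + step) - self.lp_coef(coef[mdx])
            if math.log(self.rng.random()) < delta:
                coef[mdx] += step
                resid = new_resid
                self._record(name, 1.0)
            else:
                self._record(name, 0.0)

    def _update_shift(self) -> None:
        """Joint translation of the location hierarchy.

        Proposes a common offset added to mu and the theta level (or to mu
        and psi for two-level models), leaving the conditional residuals of
        the inner levels unchanged; this breaks the slow random walk induced
        by the strong mu-theta coupling when tau is small.
        """
        if "mu" in self.fixed:
            return
        s = self.state
        d = self.scales["shift"] * self.rng.standard_normal()
        delta = self.lp_mu(s.mu + d) - self.lp_mu(s.mu)
        if self.spec.three_level:
            # theta | mu unchanged; psi-level means all shift by d
            if self.m.k:
                means = self.m.psi_means(s)
                sds = self.m.psi_sds(s)
                delta += -0.5 * float(
                    np.sum(((s.psi - means - d) ** 2 - (s.psi - means) ** 2) / sds**2)
                )
            if math.log(self.rng.random()) < delta:
                s.mu += d
                s.theta += d
                self._record("shift", 1.0)
            else:
                self._record("shift", 0.0)
        else:
            # psi | mu unchanged; the data term moves with psi
            if self.m.k:
                if self.spec.binomial:
                    delta += float(
                        np.sum(
                            self.m.loglik_treatment(s.psi + d, s.gamma)
                            - self.m.loglik_treatment(s.psi, s.gamma)
                        )
                    )
                else:
                    delta += -0.5 * float(
                        np.sum(((self.m.y - s.psi - d) ** 2 - (self.m.y - s.psi) ** 2) / self.m.s2)
                    )
            if math.log(self.rng.random()) < delta:
                s.mu += d
                s.psi = s.psi + d
                self._record("shift", 1.0)
            else:
                self._record("shift", 0.0)

    # -- sweep ----------------------------------------------------------

    def sweep(self) -> None:
        self.tries["psi"] = self.tries.get("psi", 0.0) + 1.0
        self.tries["gamma"] = self.tries.get("gamma", 0.0) + 1.0
        self._update_psi()
        self._update_gamma()
        if self.spec.three_level:
            self._update_theta(0)
            self._update_theta(1)
            self._update_tau()
            self._update_sigma(0)
            self._update_sigma(1)
        else:
            self._update_sigma(0)
        self._update_mu()
        self._update_shift()
        self._update_coefficients()

    def run(self) -> tuple[np.ndarray, dict[str, float]]:
        cfg = self.cfg
        m = self.m
        self._vec_acc = {"psi": np.zeros(m.k), "gamma": np.zeros(m.k)}
        for it in range(cfg.burn_in):
            self.sweep()
            if (it + 1) % cfg.adapt_interval == 0:
                self.adapt()
        self.acc.clear()
        self.tries.clear()
        self._vec_acc = {"psi": np.zeros(m.k), "gamma": np.zeros(m.k)}
        n_kept = cfg.iterations // cfg.thin
        out = np.empty((n_kept, len(m.param_names())))
        kept = 0
        for it in range(cfg.iterations):
            self.sweep()
            if (it + 1) % cfg.thin == 0 and kept < n_kept:
                out[kept] = m.flatten(self.state)
                kept += 1
        rates = {
            name: self.acc.get(name, 0.0) / tried
            for name, tried in self.tries.items()
            if name not in ("psi", "gamma") and tried
        }
        for vec in ("psi", "gamma"):
            tried = self.tries.get(vec, 0.0)
            if tried and self._vec_acc[vec].size:
                rates[vec] = float(np.mean(self._vec_acc[vec]) / tried)
        return out[:kept], rates


def run_mcmc(data: Dataset, spec: ModelSpec, config: MCMCConfig | None = None) -> PosteriorSamples:
    """Draw from the posterior of ``spec`` on ``data``; deterministic given the seed."""
    config = config or MCMCConfig()
    model = PreparedModel(data, spec)
    names = model.param_names()
    chains = []
    rates: dict[str, float] = {}
    for c in range(config.chains):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(c,)))
        sampler = _ChainSampler(model, config, rng)
        draws, chain_rates = sampler.run()
        chains.append(draws)
        for k, v in chain_rates.items():
            rates[k] = rates.get(k, 0.0) + v / config.chains
    return PosteriorSamples(
        draws=np.stack(chains),
        param_names=names,
        acceptance_rates=rates,
        config=config,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# diagnostics & summaries
# ---------------------------------------------------------------------------


def gelman_rubin(samples: PosteriorSamples | np.ndarray, parameter: str | None = None) -> float:
    """Potential scale reduction factor across chains (clamped below at 1).

    Accepts either a :class:`PosteriorSamples` plus a parameter name, or a raw
    (chains, draws) array.
    """
    x = samples.get(parameter) if isinstance(samples, PosteriorSamples) else np.asarray(samples)
    m, n = x.shape
    if m < 2:
        raise ValueError("the Gelman-Rubin diagnostic needs chains >= 2")
    if n < 10:
        raise ValueError("need at least 10 draws per chain")
    chain_means = x.mean(axis=1)
    W = float(np.mean(x.var(axis=1, ddof=1)))
    B = n * float(np.var(chain_means, ddof=1))
    if W == 0.0:
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    return max(1.0, math.sqrt(var_hat / W))


def effective_sample_size(samples: PosteriorSamples | np.ndarray, parameter: str | None = None) -> float:
    """ESS via Geyer's initial positive sequence on the pooled autocorrelation."""
    x = samples.get(parameter) if isinstance(samples, PosteriorSamples) else np.asarray(samples)
    x = np.atleast_2d(x)
    m, n = x.shape
    total = m * n
    if total < 100:
        raise ValueError("need at least 100 draws for an ESS estimate")
    centred = x - x.mean(axis=1, keepdims=True)
    if float(np.max(np.abs(centred))) == 0.0:
        return 1.0
    # chain-averaged autocovariance via FFT
    size = 2 ** int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(centred, n=size, axis=1)
    acov = np.fft.irfft(f * np.conj(f), n=size, axis=1)[:, :n].real / n
    rho = acov.mean(axis=0) / acov[:, 0].mean()
    # Geyer: sum consecutive pairs while positive
    summed = 0.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        summed += pair
        t += 2
    ess = total / (1.0 + 2.0 * summed)
    return float(min(max(ess, 1.0), total))


def summarize(
    samples: PosteriorSamples, parameter: str, scale: str = "log_or"
) -> Summary:
    """Median and equal-tailed 95% CrI pooled across chains.

    ``scale='or'`` exponentiates the log-scale quantiles (quantiles commute
    with monotone transforms).
    """
    if scale not in ("log_or", "or"):
        raise ValueError("scale must be 'log_or' or 'or'")
    pooled = samples.pooled(parameter)
    lo, med, hi = np.quantile(pooled, [0.025, 0.5, 0.975])
    if scale == "or":
        lo, med, hi = math.exp(lo), math.exp(med), math.exp(hi)
    return Summary(parameter=parameter, median=float(med), cri_low=float(lo), cri_high=float(hi), scale=scale)
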