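"""Posterior reports: method comparison tables, diagnostics, provenance.

A report row holds one (method, parameter) pair summarised on the odds-ratio
scale with its convergence diagnostics.  The plain-text forest table stacks
the overall effect mu and the study-type effects theta_1 (randomised) and
theta_2 (non-randomised) for each method, mirroring the usual presentation
of cross-design syntheses.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field

import pandas as pd

from .data_model import Dataset, StudyType, write_dataset
from .mcmc import MCMCConfig, PosteriorSamples, gelman_rubin, effective_sample_size, run_mcmc, summarize
from .models import Adjustment, Downweighting, Likelihood, ModelSpec
from .priors import PriorSet, PriorSpec, base_case_priors, build_informative_mu_prior

__all__ = [
    "ReportRow",
    "AnalysisReport",
    "dataset_fingerprint",
    "fit_report",
    "compare_methods",
    "canonical_specs",
    "pooled_inputs_for_informative_prior",
]


@dataclass
class ReportRow:
    method: str
    parameter: str
    median_or: float
    cri_low_or: float
    cri_high_or: float
    rhat: float
    ess: float


@dataclass
class AnalysisReport:
    rows: list[ReportRow]
    provenance: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def forest_table(self) -> str:
        """Aligned text table of OR medians and 95% CrIs per method/parameter."""
        lines = [f"{'method':<22}{'parameter':<12}{'OR':>8}  {'95% CrI':>18}  {'R-hat':>6}"]
        for r in self.rows:
            cri = f"({r.cri_low_or:.2f}, {r.cri_high_or:.2f})"
            lines.append(
                f"{r.method:<22}{r.parameter:<12}{r.median_or:>8.2f}  {cri:>18}  {r.rhat:>6.3f}"
            )
        return "\n".join(lines)


def dataset_fingerprint(data: Dataset) -> str:
    buffer = io.StringIO()
    write_dataset(data, buffer)
    return hashlib.sha256(buffer.getvalue().encode()).hexdigest()[:16]


def spec_fingerprint(spec: ModelSpec) -> str:
    return hashlib.sha256(repr(spec).encode()).hexdigest()[:16]


def _report_parameters(spec: ModelSpec) -> list[str]:
    if spec.downweighting is Downweighting.SUTTON_PRIOR or (
        spec.likelihood is Likelihood.NORMAL_TWO_LEVEL
    ):
        names = ["mu"]
    else:
        names = ["mu", "theta_1", "theta_2"]
    if spec.adjustment is Adjustment.ARM_DIFFERENCE:
        names += [f"alpha_{c}" for c in spec.covariates]
    elif spec.adjustment is Adjustment.AGGREGATE:
        names += [f"beta_{c}" for c in spec.covariates]
    return names


def fit_report(
    data: Dataset,
    spec: ModelSpec,
    config: MCMCConfig,
    method: str = "fit",
) -> tuple[AnalysisReport, PosteriorSamples]:
    """Run the sampler and summarise the reportable parameters on the OR scale.

    Bias/meta-regression coefficients are reported as odds-ratio multipliers
    per unit covariate difference (exp of the coefficient).
    """
    samples = run_mcmc(data, spec, config)
    rows = []
    for name in _report_parameters(spec):
        s = summarize(samples, name, scale="or")
        rhat = (
            gelman_rubin(samples, name) if config.chains >= 2 else float("nan")
        )
        rows.append(
            ReportRow(
                method=method,
                parameter=name,
                median_or=s.median,
                cri_low_or=s.cri_low,
                cri_high_or=s.cri_high,
                rhat=rhat,
                ess=effective_sample_size(samples, name),
            )
        )
    report = AnalysisReport(
        rows=rows,
        provenance={
            "seed": config.seed,
            "spec_hash": spec_fingerprint(spec),
            "dataset_fingerprint": dataset_fingerprint(data),
            "prior_set": spec.priors.label,
            "acceptance_rates": dict(samples.acceptance_rates),
        },
    )
    return report, samples


def pooled_inputs_for_informative_prior(
    data: Dataset, config: MCMCConfig
) -> tuple[float, float]:
    """Pooled log OR of the non-randomised studies and the posterior variance
    of the randomised pooled effect, from separate two-level fits.

    These are the ingredients of the informative-prior downweighting: the
    prior is centred on the first and given ``inflation`` times the second as
    its variance (default inflation 4).
    """
    import numpy as np

    out = {}
    for stype in (StudyType.NON_RANDOMISED, StudyType.RANDOMISED):
        subset = Dataset(data.by_type(stype), list(data.covariate_names))
        if not subset.studies:
            raise ValueError(f"no {stype.value} studies; cannot build the informative prior")
        spec = ModelSpec(likelihood=Likelihood.NORMAL_TWO_LEVEL, priors=base_case_priors())
        samples = run_mcmc(subset, spec, config)
        pooled = samples.pooled("mu")
        out[stype] = (float(np.median(pooled)), float(np.var(pooled, ddof=1)))
    return out[StudyType.NON_RANDOMISED][0], out[StudyType.RANDOMISED][1]


def canonical_specs(
    covariates: tuple[str, ...],
    priors: PriorSet | None = None,
    informative_mu: PriorSpec | None = None,
) -> dict[str, ModelSpec]:
    """The five standard comparison methods on the binomial three-level model."""
    priors = priors or base_case_priors()
    specs = {
        "unadjusted": ModelSpec(priors=priors),
        "arm_adjusted": ModelSpec(
            adjustment=Adjustment.ARM_DIFFERENCE, covariates=covariates, priors=priors
        ),
        "aggregate_adjusted": ModelSpec(
            adjustment=Adjustment.AGGREGATE, covariates=covariates, priors=priors
        ),
        "prior_constraint": ModelSpec(
            downweighting=Downweighting.PREVOST_CONSTRAINT, priors=priors
        ),
    }
    if informative_mu is not None:
        specs["informative_prior"] = ModelSpec(
            downweighting=Downweighting.SUTTON_PRIOR,
            priors=priors.with_mu(informative_mu),
        )
    return specs


def compare_methods(
    data: Dataset,
    specs: dict[str, ModelSpec],
    config: MCMCConfig,
) -> AnalysisReport:
    """Fit several methods on one dataset and stack the reports."""
    if len(specs) < 2:
        raise ValueError("a comparison needs at least two method specs")
    rows: list[ReportRow] = []
    provenance: dict = {"dataset_fingerprint": dataset_fingerprint(data), "methods": {}}
    for label, spec in specs.items():
        report, _ = fit_report(data, spec, config, method=label)
        rows.extend(report.rows)
        provenance["methods"][label] = {
            "seed": config.seed,
            "spec_hash": spec_fingerprint(spec),
            "prior_set": spec.priors.label,
        }
    return AnalysisReport(rows=rows, provenance=provenance)


def build_informative_mu_from_data(
    data: Dataset, config: MCMCConfig, inflation: float = 4.0
) -> PriorSpec:
    """Convenience wrapper: two-level fits, then the informative-prior constructor."""
    pooled_nrs, var_rct = pooled_inputs_for_informative_prior(data, config)
    return build_informative_mu_prior(pooled_nrs, var_rct, inflation)
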