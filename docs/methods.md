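# Methods

## Model family

`crossmeta` fits hierarchical models for pooling comparative binary-outcome
studies of two design types (randomised, non-randomised):

* **Binomial three-level model** (the default). Arm counts are binomial;
  the control-arm log odds γ_ij and the study log odds ratio ψ_ij are
  explicit parameters, so no continuity corrections or normal
  approximations enter. ψ_ij is drawn around the type-level effect θ_i,
  which is drawn around the population effect μ with between-type sd τ.
  Effects are odds ratios throughout; a relative-risk link is out of scope.
* **Normal models** (two- and three-level) operate on classical log-OR
  summaries with Woolf variances (1/a + 1/b + 1/c + 1/d). A continuity
  correction of 0.5 is added to all four cells of a study's 2×2 table, only
  when some cell is zero, and only on this summary path. Tables with no
  events (or all events) in both arms carry no odds-ratio information and
  raise a degenerate-study error.

### Bias adjustment

The arm-difference adjustment replaces ψ_ij's prior mean θ_i by
θ_i + Σ_m α_m (x_mTij − x_mCij). The α_m are shared across **all** studies,
including the randomised ones, whose small imbalances help identify α; a
config switch (`include_randomised_differences=False`) restricts the term to
non-randomised studies. Raw differences are not centred or standardised:
α_m is then interpretable as mean bias per unit imbalance of confounder m.

The aggregate comparator regresses on whole-study covariate values
(sample-size-weighted across arms) centred at their across-study means, so
θ_i keeps its interpretation as the type effect at average covariate
levels. Aggregate coefficients share the same vague Normal(0, 1000) prior
as the bias coefficients.

Studies missing a required covariate are dropped from adjusted fits with a
logged warning; the imputation stage is the alternative.

### Downweighting variants

* **Prior constraint**: a joint prior indicator 1{|μ−θ₁| < |μ−θ₂|},
  enforced inside the Metropolis-Hastings acceptance (not by post-hoc
  filtering), so every retained draw satisfies it. The inequality is
  strict; the measure-zero tie counts as violated. Initialisation places
  θ₁ = μ and offsets θ₂ so the chain starts inside the support.
* **Informative prior**: the likelihood is restricted to the randomised
  studies — collapsing the hierarchy to a two-level model over those
  studies — while μ's prior is Normal(pooled non-randomised log OR,
  inflation × pooled randomised variance), inflation defaulting to 4. The
  pooled ingredients are computed by separate two-level fits per study type
  (`pooled_inputs_for_informative_prior`) rather than hard-coded; the
  Normal(−0.5619, 0.8179) prior of the motivating analysis is kept as a
  worked example and a test oracle for the constructor.

## Priors

Half-normals are parameterised by the sd-scale of the underlying
untruncated normal (variance 0.26 ⇔ scale 0.51). Shipped sets:

| parameter | base_case | prevost | vaguest |
|---|---|---|---|
| μ | Normal(0, √10) | same | same |
| τ | half-Normal(0.51) | half-Normal(0.18) | half-Normal(1.0) |
| σ₁ | half-Normal(0.51) | half-Normal(0.36) | half-Normal(1.0) |
| σ₂ | half-Normal(0.51) | half-Normal(0.36) | Uniform(0, 10) |
| γ_ij, α_m | Normal(0, √1000) | same | same |

All densities are evaluable in closed form and integrate to 1 on their
support (checked by quadrature in the tests).

## Sampler

Adaptive random-walk Metropolis-within-Gibbs:

* ψ and γ are updated as vector blocks with element-wise accept/reject —
  valid because the studies are conditionally independent given the rest.
* μ, θ_i, α_m (and aggregate coefficients) are scalar Gaussian random-walk
  updates on their conditionals.
* τ and σ_i are updated on the log scale with the Jacobian correction, and
  proposals below 1e-8 are rejected outright to keep the scale parameters
  away from numerical zero (the half-normal priors put finite density at 0,
  so chains legitimately visit small values).
* A **joint translation move** adds a common offset to μ and the θ level
  (or to μ and ψ in two-level models). Without it, μ mixes very slowly
  whenever τ is small, because the μ-conditional has sd ≈ τ/√2 while μ's
  marginal can be orders of magnitude wider. The translation leaves the
  inner-level residuals unchanged and restores effective sample sizes of
  thousands for μ on runs of 20 000 draws.

Proposal scales adapt by Robbins-Monro toward acceptance 0.44 every 50
iterations **during burn-in only** and are frozen afterwards, so the
post-burn-in kernel is a fixed, valid MCMC kernel. Runs are deterministic
given (seed, config, data, spec); chains use independent seed streams.
The shipped production default is two chains of 100 000 burn-in + 100 000
retained draws, matching standard practice for this model class; the test
suite and the acceptance script use 800–5 000 burn-in and 1 500–20 000
retained draws, which the diagnostics show is ample for the 44-study
problems they run (R-hat < 1.01, μ-ESS in the hundreds to thousands).

Diagnostics: classic between-chain Gelman-Rubin R-hat, clamped below at 1
so that identical chains report exactly 1.0; effective sample size by
Geyer's initial-positive-sequence estimator on the chain-averaged
autocorrelation (floored at 1 for degenerate draws). Summaries are pooled
across chains: median and equal-tailed 2.5/97.5% quantiles with linear
(type-7) interpolation; odds-ratio-scale intervals exponentiate the
log-scale quantiles (quantiles commute with monotone maps). Convergence
policy documented for users: require R-hat < 1.05 on reported parameters.

## Imputation

Missing per-arm covariate cells (assumed MCAR) are filled by: (1) a
bootstrap draw from the column's observed values, then (2) Gauss-Seidel
sweeps of OLS regression of each partially observed column on all other
covariate columns, re-predicting missing cells until the largest change is
below `convergence_tol` (default 1e-4) or `max_sweeps` (default 300 — the
near-collinearity of the paired `_T`/`_C` columns makes convergence
geometric but slow, ratio ≈ 0.93 on typical data). Proportion-type
predictions are clamped to [0, 1]. All covariates are treated as
continuous; a logistic treatment of proportions is deferred. Observed
cells are never altered. Three imputed datasets are returned by default;
callers choose one or fit each — the package does not silently pool.

## Synthetic data

The generator runs the binomial model forward with configurable truth. The
default `base_case_config` emulates a 4-randomised + 40-non-randomised
review of endovascular vs open aneurysm repair: control-arm mortality
around 4.7% (γ ~ Normal(−3, 0.7)), arm sizes uniform on [50, 500], truth
μ = ln 0.37, τ = 0.1, σ = (0.15, 0.3), and three confounders whose mean
arm imbalances match the published averages (proportion male 0.05/0.09,
age 0.82/2.40 years, cardiac disease 0.05/0.12 for randomised /
non-randomised), with bias coefficients α = (1.0, 0.05, 1.0) so the
non-randomised imbalance pattern is worth ≈ +0.33 on the log-odds scale —
the same order as the shift the arm adjustment produces on the real
review. These values are illustrative calibrations, not recovered ground
truth. `imputed_case_config` adds pulmonary/renal disease with realistic
missingness (25–54%) over 4 + 75 studies.

Per-arm covariate values are (study mean) ± (difference/2), so the
recorded arm difference equals the drawn difference exactly; proportion
study means are drawn on the logit scale, and the difference is shrunk in
the rare case an arm value would leave [0, 1]. `generate_confounded`
shifts each non-randomised imbalance mean by strength × its baseline mean
(falling back to the imbalance sd when the mean is zero) and records the
induced bias Σ α_m · shift_m; strength 0 reproduces `generate` bit-for-bit.

What the generator does **not** emulate: real reviews have correlated
covariates, non-binomial overdispersion, selective reporting, and
covariates missing not-at-random. Passing recovery tests therefore show
the machinery is correct under the stated model, not that adjustment
removes confounding in arbitrary real data — in particular, adjustment can
only address measured confounders.

## Validation properties and known limitations

The acceptance suite checks: sampler agreement with the closed-form
conjugate posterior (fixed-variance normal model); prior recovery on an
empty dataset; exact reduction of the adjusted to the unadjusted model on
balanced data; constraint satisfaction in 100% of retained draws and the
downweighting pull toward the randomised estimate (a tendency, checked by
majority over replicates — shrinkage can leave θ₁ ≈ θ₂, giving the
constraint no directional leverage on a given dataset); 50-replicate
recovery of μ and α; the bias-reduction ordering (arm adjustment beats
both comparators on confounded data in ≈ 88% of replicates); imputation
recovery under 30% MCAR masking; and the informative-prior constructor.

A documented property of the default study conditions: with only two
study types, τ is barely identified and its half-Normal(0.51) prior
dominates, so μ's 95% credible interval is far wider (≈ 1.5 on the log-OR
scale, matching what the model produces on real reviews of this shape)
than the typical estimation error, and fixed-truth coverage at the default
τ_true = 0.1 is ≈ 100% — conservative rather than miscalibrated. When the
generating τ matches the prior's typical scale (τ_true = 0.4), the same
pipeline attains nominal ≈ 95% coverage (recomputed by
`scripts/acceptance.py` as `mu_cri_coverage_pct_moderate_tau`). Users
should read μ's interval under these priors as deliberately conservative
when few design types are available.
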