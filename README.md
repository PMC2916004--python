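# crossmeta

Bayesian synthesis of treatment-effect evidence from **randomised and
non-randomised comparative studies**, with bias adjustment for covariate
imbalances between study arms.

Health-technology assessments often need to pool a handful of randomised
trials with a much larger body of observational evidence. Non-randomised
studies, lacking randomisation, can carry arm-level imbalances in prognostic
factors (age, sex, comorbidity) that confound their effect estimates.
`crossmeta` implements a three-level hierarchical model for this setting,
the study-specific bias-adjustment term that corrects each study's log odds
ratio in proportion to its measured between-arm imbalances, and the standard
comparator approaches (no adjustment, aggregate-value meta-regression, and
two ways of downweighting non-randomised evidence), together with an MCAR
multiple-imputation stage for missing covariates and a synthetic-data
generator for validation studies.

## The model

Arm counts are binomial. For study *j* of type *i* (1 = randomised,
2 = non-randomised), with treatment/control events *r<sub>Tij</sub>*,
*r<sub>Cij</sub>* out of *n<sub>Tij</sub>*, *n<sub>Cij</sub>*:

```
r_Cij ~ Binomial(n_Cij, p_Cij),   logit(p_Cij) = γ_ij
r_Tij ~ Binomial(n_Tij, p_Tij),   logit(p_Tij) = γ_ij + ψ_ij

ψ_ij ~ Normal( θ_i + Σ_m α_m (x_mTij − x_mCij),  σ_i² )
θ_i  ~ Normal( μ, τ² )
```

ψ<sub>ij</sub> is the study's log odds ratio; the novelty is the bias term
**α<sub>m</sub>(x<sub>mTij</sub> − x<sub>mCij</sub>)**: each study's expected
effect is shifted in proportion to its between-arm difference in the *m*-th
confounder, with the bias coefficients α<sub>m</sub> shared across all
studies. A perfectly balanced study is unadjusted; imbalanced studies are
corrected by the amount the ensemble of imbalances predicts. Comparators:

- **aggregate adjustment** — meta-regression on whole-study covariate values
  (mean age, proportion male), centred at their across-study means; cannot
  fix within-study imbalance;
- **prior constraint** — joint prior indicator |μ−θ₁| < |μ−θ₂| asserting the
  randomised type-effect sits closer to the population effect;
- **informative prior** — likelihood restricted to the randomised studies,
  with μ given a Normal prior centred on the pooled non-randomised estimate
  and variance 4× the randomised pooled variance.

Inference is by an adaptive Metropolis-within-Gibbs sampler (production
default: two chains, 100 000 burn-in + 100 000 retained), with the
Gelman-Rubin R-hat, effective sample size, and median + equal-tailed 95%
credible-interval summaries on the odds-ratio scale. Three prior sets ship:
`base_case` (half-Normal(0.51) sds, Normal(0, √10) μ), `prevost`
(half-Normal 0.36/0.18 sds), and `vaguest` (half-Normal(1), Uniform(0,10)
for the non-randomised sd).

## Worked example

```python
import crossmeta as cm
from crossmeta.models import ModelSpec, Adjustment

# a 4 + 40 study synthetic review with known truth (overall OR = 0.37)
data, truth = cm.generate_confounded(cm.base_case_config(seed=7), 1.0)

mc = cm.MCMCConfig(burn_in=2000, iterations=4000, chains=1, seed=5)
for label, spec in cm.canonical_specs(("male", "age", "cardiac")).items():
    s = cm.run_mcmc(data, spec, mc)
    m = cm.summarize(s, "mu")       # log-OR scale
    print(f"{label:20s} mu={m.median:+.3f}  err={abs(m.median - truth.mu):.3f}")
```

prints

```
unadjusted           mu=-0.502  err=0.492
arm_adjusted         mu=-0.749  err=0.246
aggregate_adjusted   mu=-0.522  err=0.472
prior_constraint     mu=-0.572  err=0.422
```

The generator planted a non-randomised arm-imbalance pattern worth +0.33 on
the log-odds scale (truth μ = ln 0.37 ≈ −0.994). The unadjusted and
aggregate-adjusted fits absorb that bias almost whole; the arm-difference
adjustment removes most of it; the prior constraint recovers a little by
leaning on the four randomised studies. (Across 25 such replicates the arm
adjustment gives the smallest error in ≈ 88% — see the acceptance script.)

The same analyses run from the shell:

```bash
crossmeta simulate sim.cfg out/       # CSV + ground-truth sidecar
crossmeta fit out/dataset.csv model.cfg results/
crossmeta compare out/dataset.csv results/ --methods unadjusted,arm_adjusted
crossmeta impute gappy.csv imputed/
```

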