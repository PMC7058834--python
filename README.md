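# cpgmr

Causal-inference toolkit for the smoking → DNA-methylation → lung-function
question: two-sample Mendelian randomization (MR) from GWAS/mQTL summary
statistics, directionality testing, MR mediation analysis, pleiotropy
sensitivity analyses, and three-trait Bayesian colocalization — together with
a synthetic-data generator that produces summary statistics under known
causal structures so every stage of the pipeline can be validated against
ground truth.

## Who this is for

Genetic epidemiologists asking whether DNA methylation at smoking-associated
CpG sites causally affects lung function (FEV1, in SD units), whether the
effect runs in the claimed direction, how much of it is mediated by smoking
behaviour, and whether methylation, nearby gene expression and lung function
share a single causal variant at a locus.

## The statistics at the core

- **Wald ratio / IVW.** For an mQTL with SNP-methylation effect β̂GP and
  SNP-FEV1 effect β̂GD, the causal effect is β̂GD/β̂GP with a delta-method SE
  (first- or second-order). Multiple conditionally independent mQTLs are
  combined by fixed-effects inverse-variance weighting; a
  weak-instrument-robust confidence interval is available by score-test
  inversion (Fieller/Anderson–Rubin form).
- **Pleiotropy sensitivity.** MR-Egger (slope + intercept test), the
  weighted-median estimator, Cochran's Q with modified second-order weights,
  the MR-PRESSO global test, and a generalized-least-squares IVW that uses
  the LD correlation matrix of instruments in linkage disequilibrium
  (ρ² < 0.8).
- **Directionality.** The MR Steiger test compares the variance the
  instruments explain in exposure versus outcome via
  r² = z²/(z² + n − 2) and Fisher's z transform.
- **Mediation.** Two-step MR: indirect effect θ₁·θ₂ (product of
  coefficients) with delta-method SE; multivariable MR gives direct effects,
  hence the difference-of-coefficients indirect estimate total − direct;
  proportion mediated = indirect/total = θ₁θ₂/(θ₃ + θ₁θ₂).
- **Colocalization.** Wakefield approximate Bayes factors per variant and
  trait; all 15 sharing configurations of three traits (every set partition
  of every trait subset); per-variant priors p₁ = 1e-4, p₂ = 1e-6,
  p₃ = 1e-7; posterior probability of association (PPA), with PPA ≥ 80%
  read as evidence of a shared causal variant.

## Worked example

```python
from cpgmr import (SimConfig, simulate_study, select_instruments, harmonize,
                   wald_ratios, ivw_fixed, ivw_test_inversion_ci,
                   steiger_from_harmonized, simulate_region, moloc_posteriors)

cfg = SimConfig(seed=7, dag="M_to_Y")     # methylation -> FEV1, effect -0.085 SD
study = simulate_study(cfg)                # n1 = 846 mQTL sample, n2 = 50,000 GWAS
instruments = select_instruments(study.sample1["M"])       # p < 1e-7 mQTLs
h = harmonize(instruments, study.sample2["Y"])
fit = ivw_fixed(wald_ratios(h, se_order="second"))
lo, hi = ivw_test_inversion_ci(h)
st = steiger_from_harmonized(h)

region, truth = simulate_region(SimConfig(seed=7), "abc")  # one shared variant
res = moloc_posteriors(region)
```

This prints (via the obvious `print` calls):

```
true total effect: -0.085
instruments passing p<1e-7: ['rs1', 'rs2', 'rs3']
IVW estimate: -0.0910 (SE 0.0085, p = 5.01e-27)
95% robust CI: [-0.1148, -0.0724]
Steiger: r2_exp = 0.395, r2_out = 0.00341, direction = exposure_to_outcome, p = 2.56e-85
shared-variant region: PPA(abc) = 0.964, top configuration = abc
```

The IVW estimate recovers the simulated −0.085 SD effect within its CI; the
Steiger test reads the direction correctly because the three mQTLs explain
~40% of methylation but only ~0.3% of the outcome; and the colocalization
posterior concentrates on the all-three-share configuration for a region
where one variant truly drives all traits.

A CLI mirrors the staged analysis (`cpgmr simulate | discover | replicate |
bidirectional | mediate | sensitivity | coloc | report`); run
`cpgmr --help` for options.

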