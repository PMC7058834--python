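# Methods

This note documents the statistical model behind `cpgmr`, the choices made
where the design was genuinely open, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## Two-sample MR model

Summary statistics come from two non-overlapping samples: SNP–methylation
effects β̂GP (SD of methylation per effect-allele copy) from a small mQTL
cohort, and SNP–outcome effects β̂GD (SD of FEV1, or of lifetime smoking,
per allele) from a large GWAS. For one instrument the causal effect of
methylation on the outcome is the Wald ratio β̂GD/β̂GP. Its SE is the delta
method at first order (se_GD/|β̂GP|; default, because single studies weight
by outcome-side inverse variance) or second order (adds the
β̂GD²·se_GP²/β̂GP⁴ term; recommended whenever the exposure sample is small).
Conditionally independent instruments are combined by fixed-effects IVW;
p-values use the normal distribution throughout, since all source samples
are large.

**Weak-instrument behaviour.** At the study conditions emulated here
(exposure n ≈ 846, per-mQTL r² between 2.9% and 31.3%, so exposure z-scores
down to ~5) the delta-method interval genuinely undercovers: measured
coverage is ≈ 89% at a nominal 95%, with the z-statistics overdispersed by
~10%, whichever SE order is used. This is a property of the ratio estimator,
not of the implementation. The package therefore also provides
`ivw_test_inversion_ci`, which inverts the score statistic
T(θ) = Σⱼ (β̂GD,j − θ β̂GP,j)²/(se_GD,j² + θ² se_GP,j²) ~ χ²(L) under H₀ —
a Fieller/Anderson–Rubin interval that is exact under normal summary
statistics at any instrument strength. The parameter-recovery study
evaluates this interval; the delta intervals remain available and their
undercoverage at small exposure samples is the documented caveat.

## Harmonization

Outcome records are re-expressed on the exposure's effect allele: swapped
labels flip the sign (and fold the allele frequency); non-palindromic SNPs
are also matched across strand complements. Strand-ambiguous A/T and C/G
SNPs are kept only when both allele frequencies are on the same side of 0.5
and outside [0.42, 0.58] — the common two-sample MR convention; the original
analyses do not state a harmonization rule, so this is a package convention,
not a reproduction. Every exclusion carries a machine-readable reason.
Instrument strength is summarized per SNP as r² = z²/(z² + n − 2) and
F = z²; the two are tied by F = r²(n−2)/(1−r²).

## Pleiotropy and heterogeneity diagnostics

- **Cochran's Q** over per-SNP ratios with first-order weights
  β̂GP²/se_GD², or modified second-order weights
  1/(se_GD²/β̂GP² + θ̂²·se_GP²/β̂GP²) where θ̂ is the pooled IVW estimate and
  the weights are iterated to their fixed point. Plugging each SNP's own
  noisy ratio into the second-order term instead makes the test markedly
  conservative (type-I ≈ 1.5% at nominal 5% in our null simulations); the
  pooled-estimate form restores calibration (≈ 4.5–5%).
- **MR-PRESSO global test**: observed statistic is the weighted residual sum
  of squares about leave-one-out IVW slopes; the null distribution is built
  by parametric resampling of both exposure and outcome betas. Empirical
  p-values use the +1 correction (floor 1/(n_sim+1)). Only the global test
  is implemented — not the outlier or distortion follow-ups.
- **MR-Egger**: weighted regression with unconstrained intercept after
  orienting all SNPs to non-negative exposure betas (required for
  identifiability). SEs follow the fixed-effect convention
  sqrt(diag((XᵀWX)⁻¹)) with no dispersion scaling, matching the brute-force
  normal-equations oracle in the tests. At small exposure samples the Egger
  slope suffers regression dilution proportional to the ratio of
  exposure-beta noise to instrument-strength spread; the recovery tests run
  at a design where this is negligible, and the effect is the reason Egger
  estimates from an 846-person exposure sample should be read as
  conservative.
- **Correlated instruments**: generalized weighted least squares through the
  origin with Ω = diag(se_GD)·ρ·diag(se_GD) from a supplied LD matrix;
  pairs at ρ² ≥ 0.8 are pruned (the member with the weaker exposure
  association is dropped) before fitting.
- **Weighted median**: midpoint-cumulative-weight interpolation of the
  sorted ratios; SE from a seeded parametric bootstrap (default 1000
  resamples; the seed is a required argument so results are reproducible).

## Steiger directionality

r² is computed per trait from summary z-scores and summed over conditionally
independent instruments (capped below 1); the two correlations are compared
with Fisher's z. The known caveat applies: with very unequal sample sizes or
differential measurement precision the test can mislead; no correction is
attempted, matching the analysis this package models.

## Mediation

Two-step MR: θ̂₁ (exposure→mediator, exposure's instruments) and θ̂₂
(mediator→outcome, mediator's instruments) multiply into the indirect
effect; the delta-method SE takes cov(θ̂₁, θ̂₂) = 0, justified by the
non-overlapping samples at each step. MVMR fits outcome betas on both
exposures' beta columns (weighted, no intercept); the difference method is
total − direct with independence-assumed SEs. The proportion mediated is
reported with a validity flag (rather than suppressed) when the indirect and
total effects disagree in sign.

The difference-of-coefficients estimate is attenuation-biased when the
exposure-beta matrix is measured in a small sample (errors-in-variables in
the MVMR regressors): with an 846-person methylation sample the paired
product-vs-difference discrepancy is of order 0.006 on an indirect effect of
−0.015, shrinking roughly with 1/n of the exposure sample. The consistency
test therefore checks that the two sampling distributions overlap, and the
simulation studies report the product method as the headline. The recovered
proportion mediated is summarized as mean(indirect)/mean(total) across
replicates (ratio of means, not mean of ratios) with a delta-method
Monte-Carlo SE, which avoids per-replicate ratio noise bias.

## Colocalization

Per variant and trait, the Wakefield log-ABF is
0.5·log(V/(V+W)) + z²W/(2(V+W)) with V the squared SE and W the squared
effect-prior SD (default 0.15 for all quantitative traits, configurable per
trait; no averaging over several W values). Configurations are every set
partition of every subset of the traits (15 for three traits). A
configuration's likelihood sums, over assignments of *distinct* variants to
blocks, the product of block ABFs — computed exactly by inclusion–exclusion
in a max-shifted linear space (regions are at most a few hundred variants,
so the exact sums are cheap and |z| > 30 cannot overflow). Per-variant
priors p₁ = 1e-4, p₂ = 1e-6, p₃ = 1e-7 multiply per block; the null carries
weight 1; posteriors normalize over all configurations. Regions qualify with
≥ 50 variants at MAF ≥ 5% with complete statistics for every trait. The
headline `ppa_three_way` is the posterior of the single-block "abc"
configuration, and the full posterior vector is always reported, since a
single summary PPA under-determines which sharing pattern drove it;
`ppa_meth_fev1` additionally sums every configuration in which methylation
and lung function share a block. The per-gene scan runs the analysis for
every candidate gene's expression statistics (genes within 1 Mb of the CpG,
interpreted as transcription start within 1 Mb) and reports the gene with
the highest three-way PPA.

## Synthetic-data generator

The generator is the package's test bed and defines its study conditions:

- **Two-sample structure**: individuals are simulated once and split before
  any regression — sample 1 (default n = 846) stands in for a small mQTL
  cohort, sample 2 (default n = 50,000) for a large outcome GWAS. A 50k
  outcome sample is a desk-scale stand-in for a 321k-person GWAS: SEs are
  ~2.5× larger but all calibration and recovery behaviour is preserved.
- **Instruments**: 3 cis-mQTLs with per-SNP r² drawn uniformly from
  (2.9%, 31.3%) — the observed mQTL range — plus 20 mediator (smoking) and
  10 outcome (lung-function) instruments with per-SNP r² in (0.05%, 0.2%),
  emulating polygenic GWAS hits. Genotypes are binomial(2, MAF) dosages,
  MAF uniform on (0.05, 0.5), with optional AR(1) latent-Gaussian LD.
- **DAGs**: `M_to_Y`, `M_to_S_to_Y`, `S_to_M_to_Y`, `pleiotropy` (direct
  SNP→outcome paths for a configurable fraction of mQTLs, InSIDE
  satisfied), `null`, `confounded` (shared confounder, no causal path).
  Default effects θ₁ = 0.1, θ₂ = −0.15, θ₃ = −0.085 give a total
  methylation→FEV1 effect of −0.1 SD (the scale of the reported CpG
  estimates) and a true proportion mediated of 15%, inside the reported
  7.85%–19.33% range. Traits are standardized to unit variance with the
  residual noise set analytically, so the recorded truth is exact
  (`noise_sd` can instead be fixed, in which case standardization is
  empirical).
- **Regions**: 200 variants, AR(1) ρ = 0.5, independent per-trait samples
  (846 / 5,000 / 20,000 for methylation / expression / lung function),
  causal variants placed per scenario label with per-trait variance
  explained (4%, 4%, 0.6%) — z-scores comparable to real cis-mQTL, eQTL and
  large-GWAS signals.

**What passing tests do and do not show.** The generator produces normal,
homoscedastic traits, independent individuals, a single LD block, no
cell-type heterogeneity, no 450k-array measurement structure, and no real
LD panel. Calibration and recovery on these data validate the estimators'
arithmetic and their stated sampling theory; they do not certify behaviour
under real-data pathologies (population stratification, array artefacts,
complex LD), which is exactly why the sensitivity diagnostics exist as
first-class outputs.

## Simulation-study sizes and numerics

The evaluation studies use 200 replicates for coverage/direction/mediation
recovery, 2000 for Q calibration and 100 (×1000 inner resamples) for
MR-PRESSO calibration, and 200 regions for colocalization calibration —
sizes at which binomial 95% bands are decisive for the checks made. The Q
and MR-PRESSO calibration studies run the outcome GWAS at n = 5,000 with 10
instruments of r² 1–5%: type-I error under the null does not depend on the
outcome-sample scale, and the smaller scale keeps the studies quick. All
randomness flows from explicit seeds (per-replicate seeds spawned below
2³¹); ties in the weighted median sort are broken stably; GLS and MVMR
solves guard against singularity with explicit condition-number checks and
named errors.

## Known limitations

- No proxy-SNP search, liftover, or reference-panel LD estimation; the LD
  matrix must be supplied (or simulated).
- MVMR supports exactly two exposures; no exposure–mediator interaction or
  natural-effect decomposition.
- MR-PRESSO outlier removal and distortion testing are out of scope.
- Colocalization assumes at most one causal variant per trait per region
  and does not model LD between the candidate causal variants of different
  blocks; loci in long-range LD deserve the same caution as in any
  single-causal-variant colocalization.
- The Steiger test's sample-size sensitivity is documented, not corrected.
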