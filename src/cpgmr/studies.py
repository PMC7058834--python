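"""Seeded end-to-end evaluation studies on synthetic data.

Each study generates data under the study conditions encoded in
:class:`~cpgmr.simulate.SimConfig`, runs the full pipeline path under test
(harmonization -> estimation -> diagnostics), and reports calibration or
parameter-recovery summaries.  These are the routines behind the
reproducibility script and the heavier end-to-end tests.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .coloc import PPA_EVIDENCE_THRESHOLD, moloc_posteriors
from .estimators import ar_statistic, ivw_fixed, wald_ratios
from .mediation import MVMRSet, difference_indirect, mvmr_fit, two_step_indirect
from .sensitivity import cochran_q, mr_presso_global, steiger_from_harmonized
from .simulate import (
    SimConfig,
    association_scan,
    simulate_genotypes,
    simulate_region,
    simulate_traits,
)
from .sumstats import harmonize, select_instruments


def spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Derive per-replicate seeds (all below 2^31) from one master seed."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def _by_id(records):
    return {r.variant_id: r for r in records}


def _subset(records, ids):
    index = _by_id(records)
    return [index[i] for i in ids if i in index]


def _instrument_ids(config: SimConfig):
    n_m = config.n_instruments_exposure
    n_s = config.n_instruments_mediator
    ids = [f"rs{j + 1}" for j in range(config.n_snps)]
    return ids[:n_m], ids[n_m : n_m + n_s], ids[n_m + n_s :]


def _scan(genotypes, pheno, rows, trait, trait_meta):
    trait_id, trait_type = trait_meta[trait]
    return association_scan(
        genotypes[rows],
        pheno[trait].to_numpy()[rows],
        trait_id=trait_id,
        trait_type=trait_type,
    )


_META = {"M": ("cg_sim", "methylation"), "S": ("smoking", "smoking"),
         "Y": ("fev1", "lung_function")}


def mr_recovery_study(
    seed: int, n_reps: int = 200, config: SimConfig | None = None
) -> dict:
    """IVW confidence-interval coverage and Steiger direction accuracy.

    Simulates the exposure -> outcome DAG, estimates the causal effect per
    replicate by IVW of second-order Wald ratios, and checks whether the 95%
    interval covers the true total effect and whether Steiger recovers the
    forward direction.  Coverage is evaluated for the test-inversion
    (Fieller/Anderson-Rubin) interval: with a methylation sample of a few
    hundred, delta-method intervals undercover even at F > 20, whereas the
    inverted score test is exact under normal summary statistics.
    """
    from scipy import stats as _stats

    base = config or SimConfig(dag="M_to_Y")
    covered = correct = used = 0
    estimates = []
    for s in spawn_seeds(seed, n_reps):
        cfg = replace(base, seed=int(s))
        rng = cfg.rng()
        genotypes, _, mafs = simulate_genotypes(cfg, rng=rng)
        pheno, truth = simulate_traits(genotypes, cfg, mafs, rng=rng)
        s1 = slice(0, cfg.n_sample1)
        s2 = slice(cfg.n_sample1, None)
        instruments = select_instruments(_scan(genotypes, pheno, s1, "M", _META))
        if not instruments:
            continue
        h = harmonize(instruments, _scan(genotypes, pheno, s2, "Y", _META))
        result = ivw_fixed(wald_ratios(h, se_order="second"))
        used += 1
        estimates.append(result.estimate)
        if ar_statistic(h, truth.total) <= _stats.chi2.ppf(0.95, len(h)):
            covered += 1
        if steiger_from_harmonized(h).direction == "exposure_to_outcome":
            correct += 1
    return {
        "n": used,
        "true_effect": base.theta3 + base.theta1 * base.theta2,
        "coverage": covered / used,
        "steiger_correct_rate": correct / used,
        "mean_estimate": float(np.mean(estimates)),
    }


def mediation_recovery_study(
    seed: int, n_reps: int = 200, config: SimConfig | None = None
) -> dict:
    """Two-step product and MVMR difference mediation on the M->S->Y DAG.

    The methylation GWAS comes from sample 1; the large sample 2 is split in
    half so the mediator and outcome GWAS are non-overlapping (a strict
    two-sample design at every step).  Mediator/outcome instruments are the
    generator's designated SNP panels, standing in for instruments
    discovered in much larger external GWAS.  The recovered proportion
    mediated is the ratio of the mean indirect to the mean total effect,
    with a delta-method Monte-Carlo SE.
    """
    base = config or SimConfig(dag="M_to_S_to_Y")
    m_ids, s_ids, _ = _instrument_ids(base)
    indirect_prod, indirect_diff, totals = [], [], []
    for s in spawn_seeds(seed, n_reps):
        cfg = replace(base, seed=int(s))
        rng = cfg.rng()
        genotypes, _, mafs = simulate_genotypes(cfg, rng=rng)
        pheno, truth = simulate_traits(genotypes, cfg, mafs, rng=rng)
        n1 = cfg.n_sample1
        half = n1 + cfg.n_sample2 // 2
        rows1, rows_a, rows_b = slice(0, n1), slice(n1, half), slice(half, None)
        m_gwas = _scan(genotypes, pheno, rows1, "M", _META)
        s_gwas = _scan(genotypes, pheno, rows_a, "S", _META)
        y_gwas = _scan(genotypes, pheno, rows_b, "Y", _META)
        m_instr = select_instruments(_subset(m_gwas, m_ids))
        if not m_instr:
            continue
        s_instr = _subset(s_gwas, s_ids)
        # step 1 (M -> S), step 2 (S -> Y) and total (M -> Y)
        step1 = ivw_fixed(wald_ratios(harmonize(m_instr, s_gwas), "second"))
        step2 = ivw_fixed(wald_ratios(harmonize(s_instr, y_gwas), "second"))
        total = ivw_fixed(wald_ratios(harmonize(m_instr, y_gwas), "second"))
        product = two_step_indirect(
            step1.estimate, step1.se, step2.estimate, step2.se,
            total=total.estimate, se_total=total.se,
        )
        # difference of coefficients via MVMR over the combined panel
        union_ids = [r.variant_id for r in m_instr] + s_ids
        m_eff = _by_id(m_gwas)
        s_eff = _by_id(s_gwas)
        y_eff = _by_id(y_gwas)
        mv = MVMRSet(
            snps=union_ids,
            beta_exposures=[[m_eff[i].beta, s_eff[i].beta] for i in union_ids],
            se_exposures=[[m_eff[i].se, s_eff[i].se] for i in union_ids],
            beta_outcome=[y_eff[i].beta for i in union_ids],
            se_outcome=[y_eff[i].se for i in union_ids],
        )
        fit = mvmr_fit(mv)
        diff = difference_indirect(
            total.estimate, total.se, float(fit.direct_effects[0]), float(fit.ses[0])
        )
        indirect_prod.append(product.indirect)
        indirect_diff.append(diff.indirect)
        totals.append(total.estimate)

    indirect_prod = np.asarray(indirect_prod)
    indirect_diff = np.asarray(indirect_diff)
    totals = np.asarray(totals)
    n = len(totals)
    mean_i, mean_t = indirect_prod.mean(), totals.mean()
    prop = float(mean_i / mean_t)
    cov = np.cov(indirect_prod, totals) / n
    # delta method for the ratio of means
    grad = np.array([1.0 / mean_t, -mean_i / mean_t**2])
    prop_se = float(np.sqrt(grad @ cov @ grad))
    paired = indirect_diff - indirect_prod
    truth_example = SimConfig(dag=base.dag, theta1=base.theta1,
                              theta2=base.theta2, theta3=base.theta3)
    true_total = truth_example.theta3 + truth_example.theta1 * truth_example.theta2
    return {
        "n": n,
        "true_proportion": truth_example.theta1 * truth_example.theta2 / true_total,
        "proportion_mediated": prop,
        "proportion_mc_se": prop_se,
        "mean_indirect_product": float(mean_i),
        "mean_indirect_difference": float(indirect_diff.mean()),
        "paired_diff_mean": float(paired.mean()),
        "paired_diff_se": float(paired.std(ddof=1) / np.sqrt(n)),
        "paired_diff_sd": float(paired.std(ddof=1)),
        "mean_total": float(mean_t),
        "true_total": true_total,
    }


def _null_calibration_config() -> SimConfig:
    # homogeneous valid instruments; type-I error does not depend on the
    # outcome-sample scale, so the GWAS side runs at reduced size
    return SimConfig(
        dag="M_to_Y",
        n_sample2=5000,
        n_instruments_exposure=10,
        n_instruments_mediator=0,
        n_instruments_outcome=0,
        r2_exposure_range=(0.01, 0.05),
    )


def _null_harmonized(cfg: SimConfig):
    rng = cfg.rng()
    genotypes, _, mafs = simulate_genotypes(cfg, rng=rng)
    pheno, _ = simulate_traits(genotypes, cfg, mafs, rng=rng)
    s1, s2 = slice(0, cfg.n_sample1), slice(cfg.n_sample1, None)
    return harmonize(
        _scan(genotypes, pheno, s1, "M", _META),
        _scan(genotypes, pheno, s2, "Y", _META),
    )


def q_calibration_study(
    seed: int, n_reps: int = 2000, alpha: float = 0.05,
    weighting: str = "modified_second_order",
) -> dict:
    """Type-I error of Cochran's Q under homogeneous valid instruments."""
    base = _null_calibration_config()
    rejections = 0
    pvalues = []
    for s in spawn_seeds(seed, n_reps):
        h = _null_harmonized(replace(base, seed=int(s)))
        _, _, p = cochran_q(h, weighting=weighting)
        pvalues.append(p)
        rejections += p < alpha
    return {
        "n": n_reps,
        "alpha": alpha,
        "rejection_rate": rejections / n_reps,
        "pvalues": np.asarray(pvalues),
    }


def presso_calibration_study(
    seed: int, n_reps: int = 100, n_sim: int = 1000, alpha: float = 0.05
) -> dict:
    """Type-I error of the MR-PRESSO global test under the null."""
    base = _null_calibration_config()
    rejections = 0
    pvalues = []
    for s in spawn_seeds(seed, n_reps):
        h = _null_harmonized(replace(base, seed=int(s)))
        _, p = mr_presso_global(h, n_sim=n_sim, seed=int(s) + 1)
        pvalues.append(p)
        rejections += p < alpha
    return {
        "n": n_reps,
        "alpha": alpha,
        "rejection_rate": rejections / n_reps,
        "pvalues": np.asarray(pvalues),
    }


def coloc_shared_study(
    seed: int, n_regions: int = 5, config: SimConfig | None = None
) -> dict:
    """Three-way PPA on regions where one variant drives all three traits."""
    base = config or SimConfig()
    ppas = []
    for s in spawn_seeds(seed, n_regions):
        region, _ = simulate_region(replace(base, seed=int(s)), "abc")
        ppas.append(moloc_posteriors(region).ppa_three_way)
    ppas = np.asarray(ppas)
    return {
        "n": n_regions,
        "ppas": ppas,
        "min_ppa": float(ppas.min()),
        "mean_ppa": float(ppas.mean()),
    }


def coloc_null_study(
    seed: int,
    n_regions: int = 200,
    scenario: str = "a,b,c",
    config: SimConfig | None = None,
) -> dict:
    """False-sharing rate: regions with all traits driven by distinct variants."""
    base = config or SimConfig()
    high = 0
    ppas = []
    for s in spawn_seeds(seed, n_regions):
        region, _ = simulate_region(replace(base, seed=int(s)), scenario)
        ppa = moloc_posteriors(region).ppa_three_way
        ppas.append(ppa)
        high += ppa >= PPA_EVIDENCE_THRESHOLD
    return {
        "n": n_regions,
        "scenario": scenario,
        "high_ppa_rate": high / n_regions,
        "ppas": np.asarray(ppas),
    }
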