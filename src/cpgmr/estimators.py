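"""Point estimators of the causal effect from harmonized summary statistics.

The single-instrument estimate is the Wald ratio beta_outcome / beta_exposure
with a delta-method SE; multiple conditionally independent instruments are
combined by fixed-effects inverse-variance weighting.  Pleiotropy-robust
alternatives (MR-Egger, weighted median) and a generalized least-squares IVW
for instruments in linkage disequilibrium complete the set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateDesignError,
    EmptyInputError,
    InsufficientInstrumentsError,
    SingularLDError,
    WeakInstrumentError,
)
from .sumstats import HarmonizedSet, LDMatrix, two_sided_p


@dataclass(frozen=True)
class RatioEstimate:
    """Wald ratio for one instrument, in outcome units per SD of exposure."""

    variant_id: str
    estimate: float
    se: float
    se_order: str = "first"

    def __post_init__(self) -> None:
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValueError("ratio se must be finite and > 0")
        if not math.isfinite(self.estimate):
            raise ValueError("ratio estimate must be finite")
        if self.se_order not in ("first", "second"):
            raise ValueError("se_order must be 'first' or 'second'")


@dataclass
class MRResult:
    """A causal-effect estimate with its diagnostics.

    ``pvalue`` is the two-sided normal tail of estimate/se (large source-GWAS
    samples make the t correction negligible).  Egger fits additionally carry
    the intercept, and multi-SNP fits a Cochran-type heterogeneity Q.
    """

    method: str
    estimate: float
    se: float
    pvalue: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pvalue: float | None = None
    q_stat: float | None = None
    q_df: int | None = None
    q_pvalue: float | None = None


def wald_ratio(
    beta_exp: float,
    se_exp: float,
    beta_out: float,
    se_out: float,
    se_order: str = "first",
    variant_id: str = "",
) -> RatioEstimate:
    """Single-instrument Wald ratio beta_out / beta_exp.

    First-order SE ignores exposure-side sampling error (se_out/|beta_exp|);
    second-order is the full delta-method SE including it.
    """
    if beta_exp == 0.0:
        raise WeakInstrumentError(f"zero SNP-exposure effect for {variant_id or 'SNP'}")
    estimate = beta_out / beta_exp
    if se_order == "first":
        se = se_out / abs(beta_exp)
    elif se_order == "second":
        se = math.sqrt(
            se_out**2 / beta_exp**2 + beta_out**2 * se_exp**2 / beta_exp**4
        )
    else:
        raise ValueError("se_order must be 'first' or 'second'")
    return RatioEstimate(variant_id=variant_id, estimate=estimate, se=se, se_order=se_order)


def wald_ratios(h: HarmonizedSet, se_order: str = "first") -> list[RatioEstimate]:
    """Per-SNP Wald ratios for a harmonized set."""
    return [
        wald_ratio(be, se, bo, so, se_order=se_order, variant_id=snp)
        for snp, be, se, bo, so in zip(
            h.snps, h.beta_exposure, h.se_exposure, h.beta_outcome, h.se_outcome
        )
    ]


def ivw_fixed(ratios: Sequence[RatioEstimate]) -> MRResult:
    """Fixed-effects inverse-variance weighted meta-analysis of Wald ratios.

    A single ratio is returned unchanged and tagged ``wald``.
    """
    if not ratios:
        raise EmptyInputError("ivw_fixed requires at least one ratio")
    if len(ratios) == 1:
        r = ratios[0]
        return MRResult(
            method="wald",
            estimate=r.estimate,
            se=r.se,
            pvalue=float(two_sided_p(r.estimate / r.se)),
            n_snps=1,
        )
    beta = np.array([r.estimate for r in ratios])
    w = np.array([1.0 / r.se**2 for r in ratios])
    estimate = float(np.sum(w * beta) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (beta - estimate) ** 2))
    q_df = len(ratios) - 1
    return MRResult(
        method="ivw",
        estimate=estimate,
        se=se,
        pvalue=float(two_sided_p(estimate / se)),
        n_snps=len(ratios),
        q_stat=q,
        q_df=q_df,
        q_pvalue=float(stats.chi2.sf(q, q_df)),
    )


def _oriented(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Flip SNPs so every exposure beta is non-negative (both betas flip)."""
    sign = np.where(h.beta_exposure < 0, -1.0, 1.0)
    return h.beta_exposure * sign, h.beta_outcome * sign


def mr_egger(h: HarmonizedSet, intercept: bool = True) -> MRResult:
    """Weighted regression of outcome betas on exposure betas.

    With the unconstrained intercept this is MR-Egger: the slope is the
    pleiotropy-adjusted causal estimate and a nonzero intercept indicates
    directional pleiotropy.  SNPs are first oriented to non-negative exposure
    effects, which the estimator requires for identifiability.  SEs follow the
    fixed-effect convention sqrt(diag((X'WX)^-1)) with weights 1/se_out^2.
    """
    if len(h) < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 SNPs, got {len(h)}")
    x, y = _oriented(h)
    if np.ptp(x) == 0.0:
        raise DegenerateDesignError("no variation in exposure betas")
    w = 1.0 / h.se_outcome**2
    design = np.column_stack([np.ones_like(x), x]) if intercept else x[:, None]
    a = design.T @ (w[:, None] * design)
    b = design.T @ (w * y)
    cov = np.linalg.inv(a)
    coef = cov @ b
    ses = np.sqrt(np.diag(cov))
    resid = y - design @ coef
    q = float(np.sum(w * resid**2))
    q_df = len(h) - design.shape[1]
    slope_i = 1 if intercept else 0
    result = MRResult(
        method="egger" if intercept else "ivw",
        estimate=float(coef[slope_i]),
        se=float(ses[slope_i]),
        pvalue=float(two_sided_p(coef[slope_i] / ses[slope_i])),
        n_snps=len(h),
        q_stat=q,
        q_df=q_df,
        q_pvalue=float(stats.chi2.sf(q, q_df)) if q_df > 0 else None,
    )
    if intercept:
        result.intercept = float(coef[0])
        result.intercept_se = float(ses[0])
        result.intercept_pvalue = float(two_sided_p(coef[0] / ses[0]))
    return result


def _interpolated_weighted_median(beta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(beta, kind="stable")
    b = beta[order]
    wn = w[order] / np.sum(w)
    s = np.cumsum(wn) - 0.5 * wn
    return float(np.interp(0.5, s, b))


def weighted_median(
    ratios: Sequence[RatioEstimate], n_boot: int = 1000, seed: int | None = None
) -> MRResult:
    """Weighted-median causal estimate (consistent if >= 50% of weight is valid).

    The estimate interpolates the sorted ratios at cumulative weight 0.5 with
    midpoint cumulative sums; the SE comes from a seeded parametric bootstrap
    that resamples each ratio from its normal distribution.
    """
    if len(ratios) < 3:
        raise InsufficientInstrumentsError(
            f"weighted median needs >= 3 ratios, got {len(ratios)}"
        )
    if seed is None:
        raise ValueError("weighted_median requires an explicit bootstrap seed")
    beta = np.array([r.estimate for r in ratios])
    se = np.array([r.se for r in ratios])
    w = 1.0 / se**2
    estimate = _interpolated_weighted_median(beta, w)
    rng = np.random.default_rng(seed)
    draws = beta + se * rng.standard_normal((n_boot, len(ratios)))
    boot = np.array([_interpolated_weighted_median(row, w) for row in draws])
    se_est = float(np.std(boot, ddof=1))
    return MRResult(
        method="weighted_median",
        estimate=estimate,
        se=se_est,
        pvalue=float(two_sided_p(estimate / se_est)),
        n_snps=len(ratios),
    )


def ar_statistic(h: HarmonizedSet, theta: float) -> float:
    """Score statistic for H0: causal effect = theta.

    T(theta) = sum_j (beta_out_j - theta beta_exp_j)^2 /
               (se_out_j^2 + theta^2 se_exp_j^2),
    chi-square with L degrees of freedom under H0 when the summary
    statistics are normal — regardless of instrument strength.
    """
    num = (h.beta_outcome - theta * h.beta_exposure) ** 2
    den = h.se_outcome**2 + theta**2 * h.se_exposure**2
    return float(np.sum(num / den))


def ivw_test_inversion_ci(
    h: HarmonizedSet, alpha: float = 0.05
) -> tuple[float, float]:
    """Weak-instrument-robust confidence interval by test inversion.

    Inverts :func:`ar_statistic` (Fieller/Anderson-Rubin style): the interval
    is {theta : T(theta) <= chi2_{L, 1-alpha}}.  Exact under normality of the
    summary statistics, unlike delta-method CIs which undercover when the
    exposure sample is small.  Returns (-inf, inf) when the acceptance region
    is unbounded (uninformative instruments).
    """
    from scipy import optimize

    q = float(stats.chi2.ppf(1.0 - alpha, len(h)))

    def excess(theta):
        return ar_statistic(h, theta) - q

    center = ivw_fixed(wald_ratios(h, se_order="second")).estimate
    if excess(center) > 0:
        # point estimate itself rejected: fall back to the grid minimum
        grid = center + np.linspace(-1.0, 1.0, 2001) * max(abs(center), 1.0)
        values = [excess(t) for t in grid]
        center = float(grid[int(np.argmin(values))])
        if excess(center) > 0:
            return (float("-inf"), float("inf"))
    span = max(abs(center), 1.0)
    lo_bracket = hi_bracket = None
    for k in range(1, 60):
        if lo_bracket is None and excess(center - k * span) > 0:
            lo_bracket = (center - k * span, center - (k - 1) * span)
        if hi_bracket is None and excess(center + k * span) > 0:
            hi_bracket = (center + (k - 1) * span, center + k * span)
        if lo_bracket and hi_bracket:
            break
    if lo_bracket is None or hi_bracket is None:
        return (float("-inf"), float("inf"))
    lo = optimize.brentq(excess, *lo_bracket)
    hi = optimize.brentq(excess, *hi_bracket)
    return (float(lo), float(hi))


def _prune_correlated(h: HarmonizedSet, ld: LDMatrix, r2_limit: float):
    """Drop the weaker member (larger exposure p) of each pair with rho^2 >= limit."""
    keep = list(range(len(h.snps)))
    p_exp = two_sided_p(h.beta_exposure / h.se_exposure)
    rho = ld.subset(h.snps).rho
    while len(keep) > 1:
        sub = rho[np.ix_(keep, keep)] ** 2
        np.fill_diagonal(sub, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] < r2_limit:
            break
        drop = keep[i] if p_exp[keep[i]] > p_exp[keep[j]] else keep[j]
        keep.remove(drop)
    return keep, rho


def ivw_correlated(
    h: HarmonizedSet, ld: LDMatrix, prune_r2: float = 0.8
) -> MRResult:
    """IVW with correlated instruments via generalized weighted regression.

    Solves the origin-forced GLS with Omega_ij = se_out_i se_out_j rho_ij.
    Pairs with rho^2 >= ``prune_r2`` are pruned first (the member with the
    larger exposure p-value is dropped), mirroring the r^2 < 0.8 inclusion
    rule for LD instruments.
    """
    keep, rho_full = _prune_correlated(h, ld, prune_r2)
    idx = np.array(keep)
    x = h.beta_exposure[idx]
    y = h.beta_outcome[idx]
    so = h.se_outcome[idx]
    rho = rho_full[np.ix_(keep, keep)]
    if len(keep) > 1:
        off = np.abs(rho - np.eye(len(keep)))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        if off[i, j] > 1.0 - 1e-12:
            raise SingularLDError(
                f"perfectly correlated pair survives pruning: "
                f"{h.snps[keep[i]]}, {h.snps[keep[j]]}"
            )
    omega = np.outer(so, so) * rho
    if np.linalg.cond(omega) > 1e12:
        raise SingularLDError("LD-weighted covariance matrix is numerically singular")
    oi_x = np.linalg.solve(omega, x)
    oi_y = np.linalg.solve(omega, y)
    xox = float(x @ oi_x)
    estimate = float(x @ oi_y) / xox
    se = xox**-0.5
    resid = y - estimate * x
    q = float(resid @ np.linalg.solve(omega, resid))
    q_df = len(keep) - 1
    return MRResult(
        method="ivw_correlated",
        estimate=estimate,
        se=se,
        pvalue=float(two_sided_p(estimate / se)),
        n_snps=len(keep),
        q_stat=q,
        q_df=q_df,
        q_pvalue=float(stats.chi2.sf(q, q_df)) if q_df > 0 else None,
    )
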