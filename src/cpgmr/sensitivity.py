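"""Heterogeneity, global pleiotropy and directionality diagnostics.

Three complementary checks on an MR fit: Cochran's Q over per-SNP ratio
estimates (with first-order or modified second-order weights), the MR-PRESSO
global test (a parametric-simulation test of the leave-one-out residual sum
of squares), and the Steiger directionality test comparing the variance the
instruments explain in exposure versus outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InsufficientInstrumentsError, InvalidInstrumentSetError
from .sumstats import HarmonizedSet, two_sided_p
from .estimators import mr_egger


@dataclass(frozen=True)
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    direction: str  # exposure_to_outcome | outcome_to_exposure | undetermined
    z_stat: float
    pvalue: float


@dataclass(frozen=True)
class PleiotropyReport:
    q_stat: float
    q_df: int
    q_pvalue: float
    presso_rss_obs: float
    presso_global_pvalue: float
    egger_intercept: float
    egger_intercept_pvalue: float


def cochran_q(
    h: HarmonizedSet, weighting: str = "first_order"
) -> tuple[float, int, float]:
    """Heterogeneity Q over per-SNP Wald ratios.

    ``first_order`` weights are beta_exp^2/se_out^2 (the NOME approximation);
    ``modified_second_order`` adds the exposure-side variance term
    beta_ivw^2 se_exp^2 / beta_exp^2, with the pooled IVW estimate and the
    weights iterated to their fixed point.  The exposure-side term restores
    calibration when the exposure sample is finite; using the pooled
    estimate rather than each noisy per-SNP ratio keeps the test from
    becoming conservative.
    """
    if len(h) < 2:
        raise InsufficientInstrumentsError("cochran_q needs >= 2 SNPs")
    ratio = h.beta_outcome / h.beta_exposure
    be2 = h.beta_exposure**2
    w = be2 / h.se_outcome**2
    ivw = float(np.sum(w * ratio) / np.sum(w))
    if weighting == "modified_second_order":
        for _ in range(200):
            w = 1.0 / (h.se_outcome**2 / be2 + ivw**2 * h.se_exposure**2 / be2)
            updated = float(np.sum(w * ratio) / np.sum(w))
            if abs(updated - ivw) < 1e-12:
                ivw = updated
                break
            ivw = updated
    elif weighting != "first_order":
        raise ValueError(f"unknown weighting {weighting!r}")
    q = float(np.sum(w * (ratio - ivw) ** 2))
    q_df = len(h) - 1
    return q, q_df, float(stats.chi2.sf(q, q_df))


def _loo_slopes(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out origin-forced IVW slopes, vectorized over SNPs."""
    sxy = np.sum(w * x * y, axis=-1, keepdims=True)
    sxx = np.sum(w * x * x, axis=-1, keepdims=True)
    return (sxy - w * x * y) / (sxx - w * x * x)


def mr_presso_global(
    h: HarmonizedSet, n_sim: int = 1000, seed: int | None = None
) -> tuple[float, float]:
    """MR-PRESSO global heterogeneity test.

    The observed statistic is the inverse-variance weighted residual sum of
    squares about the leave-one-out IVW slope for each SNP; its null
    distribution is built by parametric resampling of both exposure and
    outcome betas from their normals.  The empirical p-value uses the +1
    correction, so its floor is 1/(n_sim + 1).
    """
    if len(h) < 4:
        raise InsufficientInstrumentsError("mr_presso_global needs >= 4 SNPs")
    if seed is None:
        raise ValueError("mr_presso_global requires an explicit seed")
    x, y = h.beta_exposure, h.beta_outcome
    sx, sy = h.se_exposure, h.se_outcome
    w = 1.0 / sy**2
    beta_loo = _loo_slopes(x, y, w)
    rss_obs = float(np.sum(w * (y - beta_loo * x) ** 2))

    rng = np.random.default_rng(seed)
    xs = x + sx * rng.standard_normal((n_sim, len(h)))
    ys = beta_loo * x + sy * rng.standard_normal((n_sim, len(h)))
    beta_loo_s = _loo_slopes(xs, ys, w)
    rss_sim = np.sum(w * (ys - beta_loo_s * xs) ** 2, axis=1)
    pvalue = (1.0 + float(np.sum(rss_sim >= rss_obs))) / (n_sim + 1.0)
    return rss_obs, pvalue


def summary_r2(z, n: int) -> float:
    """Variance explained by independent instruments, summed over z-scores."""
    z2 = np.atleast_1d(np.asarray(z, dtype=float)) ** 2
    return float(np.sum(z2 / (z2 + n - 2)))


def steiger_test(z_exp, n_exp: int, z_out, n_out: int) -> SteigerResult:
    """MR Steiger directionality test.

    Computes the instrument-explained variance on each side from summary
    z-scores (r^2 = z^2/(z^2 + n - 2), summed over independent instruments),
    then compares the two correlations with Fisher's z transform.  The
    likely causal direction is from the trait with the larger r^2.
    """
    if n_exp < 4 or n_out < 4:
        raise InvalidInstrumentSetError("steiger_test requires n >= 4 on both sides")
    r2_exp = summary_r2(z_exp, n_exp)
    r2_out = summary_r2(z_out, n_out)
    for name, r2 in (("exposure", r2_exp), ("outcome", r2_out)):
        if r2 >= 1.0:
            raise InvalidInstrumentSetError(
                f"summed instrument r^2 for the {name} reaches 1 ({r2:.3f})"
            )
    denom = np.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    z_stat = float((np.arctanh(np.sqrt(r2_exp)) - np.arctanh(np.sqrt(r2_out))) / denom)
    if r2_exp > r2_out:
        direction = "exposure_to_outcome"
    elif r2_exp < r2_out:
        direction = "outcome_to_exposure"
    else:
        direction = "undetermined"
    return SteigerResult(
        r2_exposure=r2_exp,
        r2_outcome=r2_out,
        direction=direction,
        z_stat=z_stat,
        pvalue=float(two_sided_p(z_stat)),
    )


def steiger_from_harmonized(h: HarmonizedSet) -> SteigerResult:
    """Steiger test using a harmonized set's z-scores and sample sizes."""
    if h.n_exposure is None or h.n_outcome is None:
        raise InvalidInstrumentSetError("steiger needs sample sizes on both sides")
    return steiger_test(
        h.beta_exposure / h.se_exposure,
        h.n_exposure,
        h.beta_outcome / h.se_outcome,
        h.n_outcome,
    )


def pleiotropy_report(
    h: HarmonizedSet,
    weighting: str = "modified_second_order",
    n_sim: int = 1000,
    seed: int | None = None,
) -> PleiotropyReport:
    """Bundle of Q, MR-PRESSO global and Egger-intercept diagnostics."""
    q, q_df, q_p = cochran_q(h, weighting=weighting)
    rss, presso_p = mr_presso_global(h, n_sim=n_sim, seed=seed)
    egger = mr_egger(h)
    return PleiotropyReport(
        q_stat=q,
        q_df=q_df,
        q_pvalue=q_p,
        presso_rss_obs=rss,
        presso_global_pvalue=presso_p,
        egger_intercept=egger.intercept,
        egger_intercept_pvalue=egger.intercept_pvalue,
    )
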