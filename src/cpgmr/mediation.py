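"""Mediation analysis: two-step MR and multivariable MR.

Two-step MR instruments the exposure->mediator path (theta1) and the
mediator->outcome path (theta2) separately; the indirect effect is the
product theta1 * theta2 with a delta-method SE.  Multivariable MR (MVMR)
regresses outcome betas jointly on two exposure beta columns to obtain the
direct effect, from which the difference-of-coefficients indirect estimate
total - direct follows.  The proportion mediated is indirect / total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import CollinearExposuresError, InsufficientInstrumentsError
from .sumstats import two_sided_p


@dataclass
class MediationResult:
    indirect: float
    se_indirect: float
    pvalue: float
    method: str  # product | difference
    theta1: float | None = None
    se1: float | None = None
    theta2: float | None = None
    se2: float | None = None
    direct: float | None = None
    se_direct: float | None = None
    total: float | None = None
    se_total: float | None = None
    proportion_mediated: float | None = None
    proportion_valid: bool | None = None


@dataclass
class MVMRResult:
    direct_effects: np.ndarray
    ses: np.ndarray
    pvalues: np.ndarray
    conditional_strength_q: np.ndarray
    heterogeneity_q: float
    heterogeneity_df: int
    heterogeneity_pvalue: float
    n_snps: int


@dataclass
class MVMRSet:
    """Outcome betas with a two-column exposure beta matrix per SNP."""

    snps: list[str]
    beta_exposures: np.ndarray  # (L, 2)
    se_exposures: np.ndarray  # (L, 2)
    beta_outcome: np.ndarray
    se_outcome: np.ndarray

    def __post_init__(self) -> None:
        self.beta_exposures = np.asarray(self.beta_exposures, dtype=float)
        self.se_exposures = np.asarray(self.se_exposures, dtype=float)
        self.beta_outcome = np.asarray(self.beta_outcome, dtype=float)
        self.se_outcome = np.asarray(self.se_outcome, dtype=float)
        length = len(self.snps)
        if self.beta_exposures.shape != (length, 2):
            raise ValueError("beta_exposures must be (n_snps, 2)")
        if self.se_exposures.shape != (length, 2):
            raise ValueError("se_exposures must be (n_snps, 2)")
        if self.beta_outcome.shape != (length,) or self.se_outcome.shape != (length,):
            raise ValueError("outcome vectors must match the SNP list")

    def __len__(self) -> int:
        return len(self.snps)


def _proportion(indirect: float, total: float) -> tuple[float | None, bool | None]:
    if total == 0.0:
        return None, False
    proportion = indirect / total
    valid = indirect == 0.0 or math.copysign(1.0, indirect) == math.copysign(1.0, total)
    return proportion, valid


def two_step_indirect(
    theta1: float,
    se1: float,
    theta2: float,
    se2: float,
    total: float | None = None,
    se_total: float | None = None,
) -> MediationResult:
    """Product-of-coefficients indirect effect theta1 * theta2.

    The SE is the delta-method form sqrt(theta2^2 se1^2 + theta1^2 se2^2),
    taking cov(theta1_hat, theta2_hat) = 0 (the two steps are estimated in
    non-overlapping samples).  When the total effect is supplied the
    proportion mediated is reported with a validity flag that trips when the
    indirect and total effects disagree in sign.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be > 0")
    indirect = theta1 * theta2
    se_indirect = math.sqrt(theta2**2 * se1**2 + theta1**2 * se2**2)
    if se_indirect == 0.0:
        pvalue = 1.0
    else:
        pvalue = float(two_sided_p(indirect / se_indirect))
    result = MediationResult(
        indirect=indirect,
        se_indirect=se_indirect,
        pvalue=pvalue,
        method="product",
        theta1=theta1,
        se1=se1,
        theta2=theta2,
        se2=se2,
        total=total,
        se_total=se_total,
    )
    if total is not None:
        result.proportion_mediated, result.proportion_valid = _proportion(indirect, total)
    return result


def mvmr_fit(mv: MVMRSet) -> MVMRResult:
    """Multivariable MR by weighted least squares through the origin.

    Direct effects and SEs come from the weighted normal equations with
    weights 1/se_out^2 (fixed-effect convention).  ``conditional_strength_q``
    is the Q-form statistic from regressing each exposure's betas on the
    other's, a summary of conditional instrument strength reported without a
    threshold; ``heterogeneity_q`` is the weighted residual sum of squares on
    L - 2 degrees of freedom.
    """
    if len(mv) < 3:
        raise InsufficientInstrumentsError("mvmr_fit needs >= 3 SNPs")
    x = mv.beta_exposures
    w = 1.0 / mv.se_outcome**2
    zero_cols = np.all(x == 0.0, axis=0)
    if zero_cols.all():
        raise CollinearExposuresError("both exposure beta columns are zero")
    if zero_cols.any():
        # one exposure has no instrument signal: fit the other alone, report
        # the absent exposure with an infinite SE
        k = int(np.flatnonzero(~zero_cols)[0])
        xk = x[:, k]
        var_k = 1.0 / np.sum(w * xk**2)
        coef = np.zeros(2)
        coef[k] = var_k * np.sum(w * xk * mv.beta_outcome)
        ses = np.full(2, np.inf)
        ses[k] = np.sqrt(var_k)
    else:
        if np.linalg.matrix_rank(x) < 2:
            raise CollinearExposuresError("exposure beta columns are collinear")
        a = x.T @ (w[:, None] * x)
        if np.linalg.cond(a) > 1e12:
            raise CollinearExposuresError("exposure beta columns are near-collinear")
        cov = np.linalg.inv(a)
        coef = cov @ (x.T @ (w * mv.beta_outcome))
        ses = np.sqrt(np.diag(cov))
    resid = mv.beta_outcome - x @ coef
    q = float(np.sum(w * resid**2))
    q_df = len(mv) - 2

    cond_q = np.empty(2)
    for k in range(2):
        other = x[:, 1 - k]
        wk = 1.0 / mv.se_exposures[:, k] ** 2
        denom = np.sum(wk * other**2)
        slope = np.sum(wk * other * x[:, k]) / denom if denom > 0 else 0.0
        cond_q[k] = np.sum(wk * (x[:, k] - slope * other) ** 2)

    return MVMRResult(
        direct_effects=coef,
        ses=ses,
        pvalues=two_sided_p(coef / ses),
        conditional_strength_q=cond_q,
        heterogeneity_q=q,
        heterogeneity_df=q_df,
        heterogeneity_pvalue=float(stats.chi2.sf(q, q_df)) if q_df > 0 else float("nan"),
        n_snps=len(mv),
    )


def difference_indirect(
    total: float, se_total: float, direct: float, se_direct: float
) -> MediationResult:
    """Difference-of-coefficients indirect effect: total - direct.

    The SE assumes independence of the two estimates (they share instruments
    in practice, so this is an approximation and is flagged as such by the
    method tag).
    """
    if se_total <= 0 or se_direct <= 0:
        raise ValueError("standard errors must be > 0")
    indirect = total - direct
    se_indirect = math.sqrt(se_total**2 + se_direct**2)
    proportion, valid = _proportion(indirect, total)
    return MediationResult(
        indirect=indirect,
        se_indirect=se_indirect,
        pvalue=float(two_sided_p(indirect / se_indirect)),
        method="difference",
        direct=direct,
        se_direct=se_direct,
        total=total,
        se_total=se_total,
        proportion_mediated=proportion,
        proportion_valid=valid,
    )
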