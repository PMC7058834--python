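"""MR point estimators against hand arithmetic and brute-force oracles."""

import numpy as np
import pytest

from cpgmr.estimators import (
    RatioEstimate,
    ar_statistic,
    ivw_correlated,
    ivw_fixed,
    ivw_test_inversion_ci,
    mr_egger,
    wald_ratio,
    wald_ratios,
    weighted_median,
)
from cpgmr.exceptions import (
    DegenerateDesignError,
    EmptyInputError,
    InsufficientInstrumentsError,
    SingularLDError,
    WeakInstrumentError,
)
from cpgmr.sumstats import LDMatrix

from conftest import make_harmonized


class TestWaldRatio:
    def test_zero_numerator(self):
        r = wald_ratio(0.5, 0.05, 0.0, 0.01)
        assert r.estimate == 0.0 and r.se == pytest.approx(0.02)

    def test_direct_arithmetic(self):
        r = wald_ratio(0.2, 0.02, 0.1, 0.02)
        assert r.estimate == pytest.approx(0.5)
        assert r.se == pytest.approx(0.1)

    def test_second_order_se_formula(self):
        r = wald_ratio(0.2, 0.02, 0.1, 0.02, se_order="second")
        expected = np.sqrt(0.02**2 / 0.2**2 + 0.1**2 * 0.02**2 / 0.2**4)
        assert r.se == pytest.approx(expected)

    def test_second_order_se_matches_monte_carlo_sd(self, rng):
        beta_exp, se_exp, beta_out, se_out = 0.5, 0.05, 0.1, 0.02
        draws = (beta_out + se_out * rng.standard_normal(10**6)) / (
            beta_exp + se_exp * rng.standard_normal(10**6)
        )
        r = wald_ratio(beta_exp, se_exp, beta_out, se_out, se_order="second")
        assert r.se == pytest.approx(float(np.std(draws)), rel=0.05)

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(WeakInstrumentError):
            wald_ratio(0.0, 0.05, 0.1, 0.02)


class TestIVWFixed:
    def test_symmetric_pair(self):
        ratios = [RatioEstimate("a", 0.5, 0.1), RatioEstimate("b", 0.5, 0.1)]
        res = ivw_fixed(ratios)
        assert res.estimate == pytest.approx(0.5)
        assert res.se == pytest.approx(0.1 / np.sqrt(2))

    def test_hand_weighted_mean(self):
        ratios = [RatioEstimate("a", 0.2, 0.1), RatioEstimate("b", 0.6, 0.2)]
        res = ivw_fixed(ratios)
        assert res.estimate == pytest.approx(0.28)
        assert res.se == pytest.approx(1 / np.sqrt(125))

    def test_single_ratio_passes_through_as_wald(self):
        res = ivw_fixed([RatioEstimate("a", -0.101, 0.010)])
        assert res.method == "wald"
        assert res.estimate == -0.101 and res.se == 0.010

    def test_empty_raises(self):
        with pytest.raises(EmptyInputError):
            ivw_fixed([])


class TestMREgger:
    def test_exact_fit_through_origin(self):
        h = make_harmonized([0.2, 0.4, 0.6, 0.8], [0.02] * 4,
                            [0.2, 0.4, 0.6, 0.8], [0.02] * 4)
        res = mr_egger(h)
        assert res.estimate == pytest.approx(1.0, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_fit_with_offset(self):
        x = np.array([0.2, 0.4, 0.6, 0.8])
        h = make_harmonized(x, [0.02] * 4, 0.05 + x, [0.02] * 4)
        res = mr_egger(h)
        assert res.estimate == pytest.approx(1.0, abs=1e-12)
        assert res.intercept == pytest.approx(0.05, abs=1e-12)

    def test_matches_weighted_normal_equations_oracle(self, toy_harmonized):
        res = mr_egger(toy_harmonized)
        x = np.abs(toy_harmonized.beta_exposure)
        y = toy_harmonized.beta_outcome * np.sign(toy_harmonized.beta_exposure)
        w = 1.0 / toy_harmonized.se_outcome**2
        design = np.column_stack([np.ones_like(x), x])
        a = design.T @ np.diag(w) @ design
        coef = np.linalg.solve(a, design.T @ np.diag(w) @ y)
        cov = np.linalg.inv(a)
        assert res.intercept == pytest.approx(coef[0], abs=1e-9)
        assert res.estimate == pytest.approx(coef[1], abs=1e-9)
        assert res.intercept_se == pytest.approx(np.sqrt(cov[0, 0]), abs=1e-9)
        assert res.se == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-9)

    def test_statsmodels_cross_check(self, toy_harmonized):
        sm = pytest.importorskip("statsmodels.api")
        x = toy_harmonized.beta_exposure
        y = toy_harmonized.beta_outcome
        w = 1.0 / toy_harmonized.se_outcome**2
        fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        res = mr_egger(toy_harmonized)
        assert res.estimate == pytest.approx(fit.params[1], abs=1e-10)
        assert res.intercept == pytest.approx(fit.params[0], abs=1e-10)

    def test_too_few_snps_raises(self):
        h = make_harmonized([0.2, 0.4], [0.02] * 2, [0.1, 0.2], [0.02] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(h)

    def test_constant_exposure_betas_raise(self):
        h = make_harmonized([0.3] * 4, [0.02] * 4, [0.1, 0.2, 0.15, 0.12], [0.02] * 4)
        with pytest.raises(DegenerateDesignError):
            mr_egger(h)


def _median_oracle(beta, se):
    """Independent evaluation of the midpoint-interpolation weighted median."""
    order = np.argsort(beta)
    b = np.asarray(beta)[order]
    w = (1.0 / np.asarray(se)[order] ** 2)
    w = w / w.sum()
    s = np.cumsum(w) - w / 2.0
    k = int(np.searchsorted(s, 0.5))
    if k == 0:
        return float(b[0])
    return float(b[k - 1] + (b[k] - b[k - 1]) * (0.5 - s[k - 1]) / (s[k] - s[k - 1]))


class TestWeightedMedian:
    def test_constant_ratios(self):
        ratios = [RatioEstimate(str(i), 0.3, 0.1) for i in range(4)]
        assert weighted_median(ratios, seed=1).estimate == pytest.approx(0.3)

    def test_equal_weights_pick_middle(self):
        ratios = [RatioEstimate(str(i), v, 0.1) for i, v in enumerate([0.1, 0.4, 0.9])]
        assert weighted_median(ratios, seed=1).estimate == pytest.approx(0.4)

    def test_matches_interpolation_oracle(self):
        beta = [0.05, 0.22, 0.30, 0.41, 0.90]
        se = [0.10, 0.05, 0.21, 0.08, 0.30]
        ratios = [RatioEstimate(str(i), b, s) for i, (b, s) in enumerate(zip(beta, se))]
        res = weighted_median(ratios, seed=3)
        assert res.estimate == pytest.approx(_median_oracle(beta, se), abs=1e-12)

    def test_bootstrap_se_stable_across_seeds(self):
        beta = [0.05, 0.22, 0.30, 0.41, 0.90]
        se = [0.10, 0.05, 0.21, 0.08, 0.30]
        ratios = [RatioEstimate(str(i), b, s) for i, (b, s) in enumerate(zip(beta, se))]
        se_a = weighted_median(ratios, n_boot=5000, seed=11).se
        se_b = weighted_median(ratios, n_boot=5000, seed=12).se
        assert se_a == pytest.approx(se_b, rel=0.02)

    def test_requires_seed_and_enough_ratios(self):
        ratios = [RatioEstimate(str(i), 0.2, 0.1) for i in range(3)]
        with pytest.raises(ValueError):
            weighted_median(ratios)
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(ratios[:2], seed=1)


class TestTestInversionCI:
    def test_interval_contains_point_estimate(self, toy_harmonized):
        lo, hi = ivw_test_inversion_ci(toy_harmonized)
        est = ivw_fixed(wald_ratios(toy_harmonized, "second")).estimate
        assert lo < est < hi
        assert ar_statistic(toy_harmonized, lo) == pytest.approx(
            ar_statistic(toy_harmonized, hi), rel=1e-6
        )

    def test_reduces_to_wald_interval_with_strong_instruments(self):
        # negligible exposure-side noise and a single instrument: the
        # inverted score interval collapses to estimate +/- 1.96 SE
        h = make_harmonized([0.5], [1e-9], [0.05], [0.01])
        lo, hi = ivw_test_inversion_ci(h)
        est = 0.1
        half = 1.96 * 0.02
        assert lo == pytest.approx(est - half, abs=1e-3)
        assert hi == pytest.approx(est + half, abs=1e-3)

    def test_statistic_is_chi_square_scaled(self, toy_harmonized):
        # at the IVW estimate the statistic is the minimized heterogeneity
        est = ivw_fixed(wald_ratios(toy_harmonized, "second")).estimate
        assert ar_statistic(toy_harmonized, est) >= 0.0


class TestIVWCorrelated:
    def test_identity_ld_reduces_to_origin_weighted_regression(
        self, toy_harmonized, identity_ld
    ):
        res = ivw_correlated(toy_harmonized, identity_ld(toy_harmonized.snps))
        x, y = toy_harmonized.beta_exposure, toy_harmonized.beta_outcome
        w = 1.0 / toy_harmonized.se_outcome**2
        expected = np.sum(w * x * y) / np.sum(w * x * x)
        assert res.estimate == pytest.approx(expected, abs=1e-12)
        assert res.se == pytest.approx(np.sum(w * x * x) ** -0.5, abs=1e-12)

    def test_uncorrelated_pair_equals_ivw_of_first_order_ratios(self, identity_ld):
        h = make_harmonized([0.4, 0.3], [0.05, 0.05], [0.04, 0.05], [0.01, 0.02])
        res = ivw_correlated(h, identity_ld(h.snps))
        meta = ivw_fixed(wald_ratios(h, se_order="first"))
        assert res.estimate == pytest.approx(meta.estimate, abs=1e-12)
        assert res.se == pytest.approx(meta.se, abs=1e-12)

    def test_matches_explicit_gls_oracle_under_ar1(self):
        h = make_harmonized([0.5, 0.4, 0.6], [0.05] * 3,
                            [0.05, 0.035, 0.07], [0.01, 0.012, 0.009])
        rho = 0.5 ** np.abs(np.subtract.outer(np.arange(3), np.arange(3)))
        ld = LDMatrix(tuple(h.snps), rho)
        res = ivw_correlated(h, ld)
        omega = np.outer(h.se_outcome, h.se_outcome) * rho
        oi = np.linalg.inv(omega)
        x, y = h.beta_exposure, h.beta_outcome
        expected = (x @ oi @ y) / (x @ oi @ x)
        assert res.estimate == pytest.approx(expected, abs=1e-9)
        assert res.se == pytest.approx((x @ oi @ x) ** -0.5, abs=1e-9)

    def test_prunes_high_ld_pair_keeping_stronger_member(self):
        # rs1 and rs2 in near-perfect LD; rs2 is the weaker instrument
        h = make_harmonized([0.5, 0.2, 0.4], [0.05] * 3,
                            [0.05, 0.02, 0.04], [0.01] * 3)
        rho = np.array([[1.0, 0.95, 0.1], [0.95, 1.0, 0.1], [0.1, 0.1, 1.0]])
        res = ivw_correlated(h, LDMatrix(tuple(h.snps), rho))
        assert res.n_snps == 2

    def test_perfectly_correlated_surviving_pair_raises(self):
        h = make_harmonized([0.5, 0.4], [0.05] * 2, [0.05, 0.04], [0.01] * 2)
        rho = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(SingularLDError):
            ivw_correlated(h, LDMatrix(tuple(h.snps), rho), prune_r2=1.1)
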