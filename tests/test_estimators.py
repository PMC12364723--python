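"""MR estimators: worked examples, oracle equivalence, invariances."""

import numpy as np
import pytest

import statsmodels.api as sm

from medimr.estimators import (EstimatorError, cochran_q, egger, ivw_mre,
                               mvmr_ivw, p_from_or_ci, wald_ratios,
                               weighted_median)


class TestIVW:
    def test_hand_computed_example(self):
        est = ivw_mre([0.5, 1.0], [0.1, 0.2])
        assert est.beta == pytest.approx(0.6)
        assert est.q_stat == pytest.approx(5.0)
        # dispersion phi = Q/(J-1) = 5 inflates the fixed SE 0.0894427
        assert est.se == pytest.approx(0.2, rel=1e-6)

    def test_zero_heterogeneity_keeps_fixed_se(self):
        est = ivw_mre([0.7, 0.7, 0.7], [0.1, 0.2, 0.3])
        assert est.beta == pytest.approx(0.7)
        assert est.q_stat == pytest.approx(0.0, abs=1e-24)
        w = 1 / np.array([0.1, 0.2, 0.3]) ** 2
        assert est.se == pytest.approx(1 / np.sqrt(w.sum()))

    def test_single_ratio_degrades_to_wald(self):
        est = ivw_mre([0.4], [0.1])
        assert est.note == "single_snp_wald_fallback"
        assert est.beta == pytest.approx(0.4) and est.se == pytest.approx(0.1)

    def test_or_ci_identities(self):
        est = ivw_mre([0.5, 1.0], [0.1, 0.2])
        assert est.or_point == pytest.approx(np.exp(est.beta))
        assert est.or_lo == pytest.approx(np.exp(est.beta - 1.959964 * est.se))
        assert est.or_hi == pytest.approx(np.exp(est.beta + 1.959964 * est.se))

    def test_matches_zero_intercept_wls_oracle(self, rng):
        """IVW beta equals the slope of gamma_y ~ 0 + gamma_x, weights 1/se_y^2."""
        for _ in range(100):
            J = int(rng.integers(3, 30))
            gx = rng.normal(0.2, 0.1, J)
            gx[np.abs(gx) < 0.02] = 0.05
            sy = rng.uniform(0.01, 0.1, J)
            gy = 0.3 * gx + rng.normal(0, sy)
            r, s = wald_ratios(gx, None, gy, sy)
            ours = ivw_mre(r, s).beta
            fit = sm.WLS(gy, gx[:, None], weights=1 / sy**2).fit()
            assert ours == pytest.approx(fit.params[0], rel=1e-10)


class TestCochranQ:
    def test_example_and_tail(self):
        q, df, p = cochran_q([0.5, 1.0], [0.1, 0.2])
        assert q == pytest.approx(5.0) and df == 1
        assert p == pytest.approx(0.0253, abs=5e-4)

    def test_identical_ratios_give_zero(self):
        q, _, p = cochran_q([0.3, 0.3, 0.3], [0.1, 0.1, 0.2])
        assert q == pytest.approx(0.0, abs=1e-24) and p == pytest.approx(1.0)

    def test_permutation_invariant(self, rng):
        r = rng.normal(0.5, 0.2, 12)
        s = rng.uniform(0.05, 0.2, 12)
        q1, _, _ = cochran_q(r, s)
        perm = rng.permutation(12)
        q2, _, _ = cochran_q(r[perm], s[perm])
        assert q1 == pytest.approx(q2)


class TestEgger:
    def test_exact_proportionality(self):
        gx = np.array([0.1, 0.2, 0.3, 0.4])
        est = egger(gx, None, 0.3 * gx, np.full(4, 0.05))
        assert est.beta == pytest.approx(0.3)
        assert est.egger_intercept == pytest.approx(0.0, abs=1e-12)
        assert est.q_stat == pytest.approx(0.0, abs=1e-20)

    def test_orientation_invariance(self, rng):
        gx = rng.normal(0.2, 0.1, 10)
        sy = rng.uniform(0.02, 0.1, 10)
        gy = 0.02 + 0.3 * gx + rng.normal(0, sy)
        a = egger(gx, None, gy, sy)
        gx2, gy2 = gx.copy(), gy.copy()
        gx2[3] *= -1
        gy2[3] *= -1
        b = egger(gx2, None, gy2, sy)
        assert a.beta == pytest.approx(b.beta)
        assert a.egger_intercept == pytest.approx(b.egger_intercept)

    def test_refuses_under_three_snps(self):
        with pytest.raises(EstimatorError, match=">= 3"):
            egger([0.1, 0.2], None, [0.1, 0.2], [0.1, 0.1])

    def test_matches_wls_oracle_with_intercept(self, rng):
        for _ in range(100):
            J = int(rng.integers(4, 25))
            gx = np.abs(rng.normal(0.2, 0.1, J)) + 0.01
            sy = rng.uniform(0.01, 0.1, J)
            gy = 0.01 + 0.4 * gx + rng.normal(0, sy)
            ours = egger(gx, None, gy, sy)
            fit = sm.WLS(gy, sm.add_constant(gx), weights=1 / sy**2).fit()
            assert ours.egger_intercept == pytest.approx(fit.params[0], rel=1e-10)
            assert ours.beta == pytest.approx(fit.params[1], rel=1e-10)


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        est = weighted_median([1.0, 2.0, 3.0], [0.1, 0.1, 0.1], seed=1)
        assert est.beta == pytest.approx(2.0)

    def test_cumulative_weight_interpolation(self):
        # weights 0.25, 0.25, 0.5 <-> se proportional to 1/sqrt(w)
        se = 1.0 / np.sqrt(np.array([0.25, 0.25, 0.5]))
        est = weighted_median([1.0, 2.0, 10.0], se, seed=1)
        assert est.beta == pytest.approx(4.6667, abs=1e-3)

    def test_majority_valid_weight_ignores_shifted_minority(self):
        """50% breakdown: with >50% of weight on valid ratios the point
        estimate sits on the valid value."""
        ratios = [1.0] * 6 + [2.0] * 4
        se = [0.1] * 10  # equal weights: valid share 60%
        est = weighted_median(ratios, se, seed=0)
        assert est.beta == pytest.approx(1.0)

    def test_bootstrap_seeded(self):
        a = weighted_median([1, 2, 3, 4.0], [0.1] * 4, seed=7)
        b = weighted_median([1, 2, 3, 4.0], [0.1] * 4, seed=7)
        assert a.se == b.se


class TestMVMR:
    def test_k1_reduces_to_fixed_effect_ivw(self, rng):
        for _ in range(20):
            J = int(rng.integers(4, 20))
            gx = rng.normal(0.2, 0.1, J)
            gx[np.abs(gx) < 0.02] = 0.05
            sy = rng.uniform(0.01, 0.1, J)
            gy = 0.3 * gx + rng.normal(0, sy)
            mv = mvmr_ivw(gx[:, None], gy, sy)[0]
            r, s = wald_ratios(gx, None, gy, sy)
            ivw = ivw_mre(r, s)
            assert mv.beta == pytest.approx(ivw.beta, rel=1e-10)

    def test_matches_wls_oracle(self, rng):
        for _ in range(100):
            J = int(rng.integers(6, 30))
            X = rng.normal(0, 0.1, (J, 2))
            sy = rng.uniform(0.01, 0.1, J)
            gy = X @ np.array([0.3, -0.2]) + rng.normal(0, sy)
            ours = mvmr_ivw(X, gy, sy)
            fit = sm.WLS(gy, X, weights=1 / sy**2).fit()
            for k in range(2):
                assert ours[k].beta == pytest.approx(fit.params[k], rel=1e-10)

    def test_rank_deficiency_names_exposures(self):
        X = np.column_stack([np.linspace(0.1, 1, 6)] * 2)
        with pytest.raises(EstimatorError, match="rank-deficient"):
            mvmr_ivw(X, np.ones(6), np.full(6, 0.1), names=["ale", "ale_copy"])

    def test_needs_k_plus_two_snps(self):
        with pytest.raises(EstimatorError, match="K\\+2"):
            mvmr_ivw(np.ones((3, 2)), np.ones(3), np.full(3, 0.1))


class TestScaleEquivariance:
    def test_outcome_rescaling_scales_all_estimators(self, rng):
        gx = np.abs(rng.normal(0.2, 0.05, 8)) + 0.05
        sy = rng.uniform(0.02, 0.08, 8)
        gy = 0.25 * gx + rng.normal(0, sy)
        c = 3.7
        r1, s1 = wald_ratios(gx, None, gy, sy)
        r2, s2 = wald_ratios(gx, None, c * gy, c * sy)
        for a, b in [(ivw_mre(r1, s1), ivw_mre(r2, s2)),
                     (egger(gx, None, gy, sy), egger(gx, None, c * gy, c * sy)),
                     (weighted_median(r1, s1, seed=3),
                      weighted_median(r2, s2, seed=3))]:
            assert b.beta == pytest.approx(c * a.beta)
            assert b.se == pytest.approx(c * a.se, rel=1e-6)


class TestORConversions:
    def test_null_or_with_symmetric_ci(self):
        assert p_from_or_ci(1.0000001, 0.5, 2.0) == pytest.approx(1.0, abs=1e-5)

    def test_ordering_violation_raises(self):
        with pytest.raises(ValueError):
            p_from_or_ci(0.5, 0.6, 0.9)
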