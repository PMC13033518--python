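"""MR estimator suite: closed-form oracles (independent weighted-least-
squares via statsmodels), exact-proportionality identities, invariances,
bootstrap determinism, and small parameter-recovery simulations."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from medmr.estimators import (
    EstimatorError,
    cochran_q,
    ivw,
    leave_one_out,
    mr_egger,
    run_mr,
    wald_ratio,
    weighted_median,
)
from medmr.simulate import simulate_harmonized_pair

from conftest import make_pair


def ivw_oracle(bx, by, sy):
    """Independent IVW oracle: statsmodels WLS through the origin."""
    fit = sm.WLS(by, bx[:, None], weights=1.0 / sy**2).fit()
    return float(fit.params[0])


def egger_oracle(bx, by, sy):
    """Independent Egger oracle: statsmodels WLS with intercept after
    non-negative orientation."""
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    return float(fit.params[0]), float(fit.params[1])


class TestWaldRatio:
    def test_arithmetic(self):
        pair = make_pair([0.5], [0.1], se_y=0.05)
        res = wald_ratio(pair)
        assert res.beta == pytest.approx(0.2)
        assert res.se == pytest.approx(0.1)

    def test_null_outcome(self):
        res = wald_ratio(make_pair([0.5], [0.0], se_y=0.05))
        assert res.beta == 0.0
        assert res.pvalue == pytest.approx(1.0)

    def test_joint_sign_flip_invariance(self):
        a = wald_ratio(make_pair([0.5], [0.1], se_y=0.05))
        b = wald_ratio(make_pair([-0.5], [-0.1], se_y=0.05))
        assert (a.beta, a.se) == (pytest.approx(b.beta), pytest.approx(b.se))

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(EstimatorError):
            wald_ratio(make_pair([0.0], [0.1], se_y=0.05))


class TestIvw:
    def test_exact_proportionality(self, proportional_pair):
        res = ivw(proportional_pair)
        assert res.beta == pytest.approx(0.3)
        assert res.q_stat == pytest.approx(0.0, abs=1e-20)
        fixed = ivw(proportional_pair, effects_model="fixed")
        assert res.se == pytest.approx(fixed.se)  # Q = 0: models agree

    def test_three_variant_closed_form(self):
        bx = np.array([0.1, 0.2, 0.15])
        by = np.array([0.02, 0.05, 0.04])
        sy = np.array([0.01, 0.01, 0.02])
        # independent hand oracle: weighted sums
        w = 1.0 / sy**2
        expected = np.sum(bx * by * w) / np.sum(bx**2 * w)
        res = ivw(make_pair(bx, by, sy))
        assert res.beta == pytest.approx(expected, rel=1e-12)
        assert res.beta == pytest.approx(ivw_oracle(bx, by, sy), rel=1e-10)

    def test_doubling_se_y_keeps_beta_doubles_fixed_se(self):
        bx = np.array([0.1, 0.2, 0.15])
        by = np.array([0.02, 0.05, 0.04])
        sy = np.array([0.01, 0.01, 0.02])
        a = ivw(make_pair(bx, by, sy), effects_model="fixed")
        b = ivw(make_pair(bx, by, 2 * sy), effects_model="fixed")
        assert b.beta == pytest.approx(a.beta)
        assert b.se == pytest.approx(2 * a.se)

    def test_single_instrument_delegates_to_wald(self):
        res = ivw(make_pair([0.5], [0.1], se_y=0.05))
        assert res.method == "wald_ratio"

    def test_random_effects_never_reports_less_uncertainty(self, rng):
        pair = simulate_harmonized_pair(0.2, 15, rng, balanced_pleiotropy_sd=0.1)
        assert ivw(pair).se >= ivw(pair, effects_model="fixed").se

    def test_joint_sign_flip_invariance(self, rng):
        pair = simulate_harmonized_pair(0.4, 10, rng)
        flipped = pair.df.copy()
        flipped.loc[::2, ["beta_x", "beta_y"]] *= -1
        pair2 = make_pair(flipped["beta_x"], flipped["beta_y"], flipped["se_y"])
        assert ivw(pair2).beta == pytest.approx(ivw(pair).beta, rel=1e-12)


class TestCochranQ:
    def test_proportional_is_zero(self, proportional_pair):
        q, df, p = cochran_q(proportional_pair, 0.3)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert p == pytest.approx(1.0)

    def test_two_variant_arithmetic(self):
        # equal weights w = 1 (beta_x = se_y), ratios 0 and 2 about 1
        pair = make_pair([0.1, 0.1], [0.0, 0.2], se_y=0.1)
        q, df, _ = cochran_q(pair, 1.0)
        assert q == pytest.approx(2.0)
        assert df == 1

    def test_null_calibration(self, rng):
        """Under homogeneity Q exceeds its chi-square 95th percentile
        about 5% of the time."""
        R = 600
        hits = 0
        for _ in range(R):
            pair = simulate_harmonized_pair(0.0, 20, rng)
            res = ivw(pair)
            crit = sps.chi2.isf(0.05, res.q_df)
            hits += res.q_stat > crit
        rate = hits / R
        assert 0.03 <= rate <= 0.07


class TestMrEgger:
    def test_exact_linear_fit_recovered(self):
        bx = np.linspace(0.05, 0.5, 6)
        by = 0.05 + 0.4 * bx
        res = mr_egger(make_pair(bx, by, se_y=0.02))
        assert res.egger_intercept == pytest.approx(0.05, rel=1e-10)
        assert res.beta == pytest.approx(0.4, rel=1e-10)

    def test_orientation_invariance(self):
        bx = np.linspace(0.05, 0.5, 6)
        by = 0.05 + 0.4 * bx
        bx2, by2 = bx.copy(), by.copy()
        bx2[2] *= -1
        by2[2] *= -1
        a = mr_egger(make_pair(bx, by, se_y=0.02))
        b = mr_egger(make_pair(bx2, by2, se_y=0.02))
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.egger_intercept == pytest.approx(b.egger_intercept, rel=1e-12)

    def test_matches_wls_oracle_to_ten_digits(self, rng):
        for _ in range(10):
            pair = simulate_harmonized_pair(0.3, 10, rng,
                                            balanced_pleiotropy_sd=0.05)
            bx, _, by, sy = pair.arrays()
            res = mr_egger(pair)
            oracle_int, oracle_slope = egger_oracle(bx, by, sy)
            assert res.beta == pytest.approx(oracle_slope, rel=1e-10)
            assert res.egger_intercept == pytest.approx(oracle_int, rel=1e-10)

    def test_insufficient_instruments(self):
        with pytest.raises(EstimatorError):
            mr_egger(make_pair([0.1, 0.2], [0.02, 0.05], se_y=0.01))


class TestWeightedMedian:
    def test_equal_weight_median(self):
        # equal weights: plain median of the ratios
        bx = np.array([0.1, 0.1, 0.1])
        by = np.array([0.01, 0.03, 0.09])  # ratios 0.1, 0.3, 0.9
        res = weighted_median(make_pair(bx, by, se_y=0.05), n_boot=50, seed=1)
        assert res.beta == pytest.approx(0.3)

    def test_dominant_weight_variant_pins_estimate(self, rng):
        """A variant holding > 50% of total weight pins the weighted median
        near its own ratio; checked against brute force over permutations."""
        bx = np.array([1.0, 0.1, 0.1, 0.1])
        by = np.array([0.5, 0.09, 0.02, 0.01])
        sy = np.full(4, 0.05)
        w = bx**2 / sy**2
        ratios = by / bx

        def brute_force(b, wt):
            order = np.argsort(b)
            b, wt = b[order], wt[order] / wt.sum()
            cum = np.cumsum(wt) - wt / 2
            return float(np.interp(0.5, cum, b))

        expected = brute_force(ratios, w)
        for perm in ([0, 1, 2, 3], [3, 2, 1, 0], [1, 3, 0, 2]):
            res = weighted_median(
                make_pair(bx[perm], by[perm], sy[perm]), n_boot=50, seed=1
            )
            assert res.beta == pytest.approx(expected, rel=1e-12)
        # the dominant variant's ratio is 0.5; estimate interpolates to it
        assert abs(expected - 0.5) < 0.15

    def test_bootstrap_se_deterministic_for_fixed_seed(self, rng):
        pair = simulate_harmonized_pair(0.3, 8, rng)
        a = weighted_median(pair, n_boot=200, seed=7)
        b = weighted_median(pair, n_boot=200, seed=7)
        assert a.se == b.se  # bit-identical

    def test_robust_to_minority_invalid_instruments(self, rng):
        """With 40% of weight on directionally pleiotropic instruments the
        weighted median stays near truth while IVW drifts."""
        wm_est, ivw_est = [], []
        for _ in range(60):
            pair = simulate_harmonized_pair(
                0.3, 20, rng, se_y_scale=0.02, se_x_scale=0.01, mean_f=100,
                invalid_frac=0.4, pleiotropy_delta=0.2, positive_x=True,
            )
            wm_est.append(weighted_median(pair, n_boot=60, seed=5).beta)
            ivw_est.append(ivw(pair).beta)
        wm_est, ivw_est = np.array(wm_est), np.array(ivw_est)
        assert abs(wm_est.mean() - 0.3) <= 3 * wm_est.std(ddof=1)
        assert ivw_est.mean() - 0.3 > 3 * ivw_est.std(ddof=1) / np.sqrt(60)
        assert abs(wm_est.mean() - 0.3) < abs(ivw_est.mean() - 0.3)


class TestLeaveOneOut:
    def test_proportional_panel_all_equal(self, proportional_pair):
        full = ivw(proportional_pair).beta
        for _, res in leave_one_out(proportional_pair):
            assert res.beta == pytest.approx(full, rel=1e-12)

    def test_outlier_identified_by_brute_force(self):
        bx = np.array([0.1, 0.2, 0.15, 0.25, 0.1])
        by = 0.3 * bx
        by[2] = 0.4  # gross outlier ratio
        pair = make_pair(bx, by, se_y=0.02)
        results = leave_one_out(pair)
        betas = np.array([r.beta for _, r in results])
        med = np.median(betas)
        # four of five fits still contain the outlier, so the LOO median is
        # contaminated and the clean fit (outlier excluded) deviates most
        best = int(np.argmax(np.abs(betas - med)))
        assert results[best][0] == pair.df["variant_id"].iloc[2]
        assert betas[best] == pytest.approx(0.3, rel=1e-6)

    def test_counting(self):
        pair = make_pair([0.1, 0.2, 0.3], [0.03, 0.06, 0.09], se_y=0.02)
        results = leave_one_out(pair)
        assert len(results) == 3
        assert all(r.n_snp == 2 for _, r in results)


class TestRunMr:
    def test_dispatch_single_instrument(self):
        results = run_mr(make_pair([0.5], [0.1], se_y=0.05))
        assert [r.method for r in results] == ["wald_ratio"]
        assert results[0].role == "primary"

    def test_dispatch_two_instruments(self):
        results = run_mr(make_pair([0.5, 0.4], [0.1, 0.08], se_y=0.05))
        assert [r.method for r in results] == ["ivw"]

    def test_dispatch_full_suite(self, rng):
        pair = simulate_harmonized_pair(0.3, 5, rng)
        results = run_mr(pair, n_boot=50)
        assert [r.method for r in results] == ["ivw", "egger", "weighted_median"]
        assert [r.role for r in results] == ["primary", "sensitivity", "sensitivity"]

    def test_all_estimators_agree_under_exact_proportionality(
        self, proportional_pair
    ):
        results = run_mr(proportional_pair, n_boot=50)
        for r in results:
            assert r.beta == pytest.approx(0.3, rel=1e-9)

    def test_ivw_recovers_truth_in_simulation(self, rng):
        """Valid-instrument scenario: mean IVW estimate lands within three
        Monte-Carlo SDs of the true effect."""
        theta = -0.5
        est = [
            ivw(simulate_harmonized_pair(theta, 30, rng)).beta for _ in range(200)
        ]
        est = np.array(est)
        assert abs(est.mean() - theta) <= 3 * est.std(ddof=1)
        # and the residual bias is the expected mild regression dilution
        assert abs(est.mean() - theta) < 0.05 * abs(theta) + 0.02
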