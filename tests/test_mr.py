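"""MR estimators against closed forms and independent regression oracles."""

import numpy as np
import pytest
import statsmodels.api as sm

from mrchain import (SimulationConfig, cochran_q, egger, ivw,
                     simulate_effect_arrays, wald_ratio, weighted_median)
from mrchain.mr import weighted_median_point


def _random_instance(rng, k=50, true_beta=0.3):
    cfg = SimulationConfig(seed=0, n_snp=k, true_beta=true_beta,
                           plant_structure=False)
    bx, sx, by, sy, _ = simulate_effect_arrays(cfg, rng)
    return bx, sx, by, sy


class TestWaldRatio:
    def test_ratio_arithmetic(self):
        assert wald_ratio(0.10, 0.01, 0.05, 0.01).beta == pytest.approx(0.5)

    def test_null_effect_p_is_one(self):
        est = wald_ratio(0.10, 0.01, 0.0, 0.01)
        assert est.beta == 0 and est.pval == pytest.approx(1.0)

    def test_first_order_se(self):
        assert wald_ratio(0.2, 0.01, 0.1, 0.04).se == pytest.approx(0.2)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.01, 0.1, 0.01)


class TestIvw:
    def test_equal_weights_reduce_to_mean(self):
        bx = np.ones(3)
        sx = np.full(3, 0.1)
        by = np.array([0.1, 0.2, 0.3])
        sy = np.ones(3)
        est = ivw((bx, sx, by, sy), "fe")
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(1 / np.sqrt(3))

    def test_near_zero_weight_snp_reduces_to_wald(self):
        # second SNP carries ~no weight: IVW collapses to the first SNP's ratio
        bx = np.array([0.2, 0.1])
        sx = np.array([0.01, 0.01])
        by = np.array([0.06, 0.5])
        sy = np.array([0.02, 1e6])
        est = ivw((bx, sx, by, sy), "fe")
        wald = wald_ratio(0.2, 0.01, 0.06, 0.02)
        assert est.beta == pytest.approx(wald.beta, abs=1e-12)
        assert est.se == pytest.approx(wald.se, rel=1e-12)

    def test_matches_wls_through_origin_oracle(self, rng):
        bx, sx, by, sy = _random_instance(rng)
        est = ivw((bx, sx, by, sy), "fe")
        fit = sm.WLS(by, bx[:, None], weights=1 / sy**2).fit()
        assert est.beta == pytest.approx(fit.params[0], abs=1e-12)
        # statsmodels rescales by residual variance; undo for the FE se
        fe_se = fit.bse[0] / np.sqrt(fit.scale)
        assert est.se == pytest.approx(fe_se, rel=1e-10)

    def test_mre_se_never_below_fe_se(self, rng):
        for _ in range(20):
            bx, sx, by, sy = _random_instance(rng, k=10)
            assert ivw((bx, sx, by, sy), "mre").se >= ivw((bx, sx, by, sy), "fe").se

    def test_sign_flip_equivariance(self, rng):
        bx, sx, by, sy = _random_instance(rng, k=10)
        flip = rng.choice([-1.0, 1.0], 10)
        a = ivw((bx, sx, by, sy), "mre")
        b = ivw((bx * flip, sx, by * flip, sy), "mre")
        assert a.beta == pytest.approx(b.beta, abs=1e-14)
        assert a.se == pytest.approx(b.se, abs=1e-14)

    def test_single_snp_rejected(self):
        with pytest.raises(ValueError, match="wald"):
            ivw((np.array([0.1]), np.array([0.01]),
                 np.array([0.05]), np.array([0.01])), "fe")


class TestEgger:
    def test_recovers_line_with_tiny_noise(self, rng):
        bx = np.linspace(0.05, 0.3, 20)
        sx = np.full(20, 1e-4)
        sy = np.full(20, 0.01)
        by = 0.02 + 0.4 * bx + rng.normal(0, 1e-5, 20)
        est = egger((bx, sx, by, sy))
        assert est.beta == pytest.approx(0.4, abs=1e-3)
        assert est.extras["intercept"] == pytest.approx(0.02, abs=1e-3)

    def test_matches_statsmodels_wls_oracle(self, rng):
        bx, sx, by, sy = _random_instance(rng, k=30)
        sign = np.where(bx < 0, -1.0, 1.0)
        x, y = bx * sign, by * sign
        fit = sm.WLS(y, sm.add_constant(x), weights=1 / sy**2).fit()
        est = egger((bx, sx, by, sy))
        assert est.beta == pytest.approx(fit.params[1], abs=1e-12)
        assert est.se == pytest.approx(fit.bse[1], rel=1e-10)
        assert est.pval == pytest.approx(fit.pvalues[1], rel=1e-8)
        assert est.extras["intercept"] == pytest.approx(fit.params[0], abs=1e-12)
        assert est.extras["intercept_se"] == pytest.approx(fit.bse[0], rel=1e-10)
        assert est.extras["intercept_p"] == pytest.approx(fit.pvalues[0], rel=1e-8)

    def test_equals_ivw_when_data_through_origin(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.5 * bx  # exact line through the origin -> intercept exactly 0
        sx = np.full(4, 0.01)
        sy = np.full(4, 0.02)
        e = egger((bx, sx, by, sy))
        i = ivw((bx, sx, by, sy), "fe")
        assert e.extras["intercept"] == pytest.approx(0.0, abs=1e-14)
        assert e.beta == pytest.approx(i.beta, abs=1e-12)

    def test_directional_pleiotropy_detected(self, rng):
        # strong spread-out instruments: NOME holds, intercept test has power
        k = 50
        gamma = rng.uniform(0.05, 0.30, k)
        sx = np.full(k, 0.005)
        sy = np.full(k, 0.02)
        bx = gamma + rng.normal(0, sx)
        by = 0.3 * gamma + rng.normal(0.05, 0.02, k) + rng.normal(0, sy)
        assert egger((bx, sx, by, sy)).extras["intercept_p"] < 0.05

    def test_too_few_instruments_rejected(self):
        with pytest.raises(ValueError):
            egger((np.array([0.1, 0.2]), np.array([0.01] * 2),
                   np.array([0.05, 0.1]), np.array([0.01] * 2)))


class TestWeightedMedian:
    def test_equal_weights_odd_k_is_sample_median(self):
        r = np.array([0.1, 0.2, 0.9])
        assert weighted_median_point(r, np.ones(3)) == pytest.approx(0.2)

    def test_dominant_weight_pins_estimate(self):
        r = np.array([0.1, 0.5, 0.9])
        w = np.array([0.01, 0.98, 0.01])
        assert weighted_median_point(r, w) == pytest.approx(0.5)

    def test_full_estimator_equal_weight_reduction(self):
        bx = np.ones(3)
        sx = np.full(3, 0.01)
        sy = np.ones(3)
        by = np.array([0.1, 0.2, 0.9])
        est = weighted_median((bx, sx, by, sy), n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.2)
        assert est.se > 0

    def test_seed_mandatory_and_reproducible(self):
        bx = np.array([0.1, 0.2, 0.3, 0.15])
        sx = np.full(4, 0.01)
        by = np.array([0.05, 0.11, 0.14, 0.08])
        sy = np.full(4, 0.02)
        with pytest.raises(ValueError):
            weighted_median((bx, sx, by, sy), n_boot=100)
        a = weighted_median((bx, sx, by, sy), n_boot=100, seed=3)
        b = weighted_median((bx, sx, by, sy), n_boot=100, seed=3)
        assert a.beta == b.beta and a.se == b.se

    def test_robust_to_minority_invalid_instruments(self, rng):
        # 40% of instruments get large orientation-aligned pleiotropy;
        # the weighted median should beat IVW nearly always
        closer = 0
        for _ in range(200):
            cfg = SimulationConfig(seed=0, n_snp=30, true_beta=0.3,
                                   plant_structure=False)
            bx, sx, by, sy, _ = simulate_effect_arrays(cfg, rng)
            inv = rng.choice(30, 12, replace=False)
            by = by.copy()
            by[inv] += np.sign(bx[inv]) * rng.uniform(0.1, 0.3, 12)
            wm = weighted_median_point(by / bx, bx**2 / sy**2)
            iv = ivw((bx, sx, by, sy), "fe").beta
            closer += abs(wm - 0.3) < abs(iv - 0.3)
        assert closer / 200 >= 0.90


class TestCochranQ:
    def test_identical_ratios_give_zero(self):
        bx = np.array([0.1, 0.2, 0.4])
        by = 0.5 * bx
        het = cochran_q((bx, np.full(3, 0.01), by, np.full(3, 0.02)))
        assert het.Q == pytest.approx(0.0, abs=1e-20)
        assert het.p_q == pytest.approx(1.0)

    def test_two_snp_unit_weight_arithmetic(self):
        # w_j = bx²/sy² = 1; ratios (0, 1); reference 0.5 -> Q = 0.5
        bx = np.ones(2)
        by = np.array([0.0, 1.0])
        het = cochran_q((bx, np.full(2, 0.01), by, np.ones(2)), ref_beta=0.5)
        assert het.Q == pytest.approx(0.5)
        assert het.df == 1

    def test_sign_flip_invariance(self, rng):
        cfg = SimulationConfig(seed=0, n_snp=10, plant_structure=False)
        bx, sx, by, sy, _ = simulate_effect_arrays(cfg, rng)
        flip = rng.choice([-1.0, 1.0], 10)
        a = cochran_q((bx, sx, by, sy))
        b = cochran_q((bx * flip, sx, by * flip, sy))
        assert a.Q == pytest.approx(b.Q, rel=1e-12)


def test_odds_ratio_reporting():
    est = ivw((np.array([1.0, 1.0]), np.array([0.1, 0.1]),
               np.array([0.2, 0.2]), np.array([0.1, 0.1])), "fe")
    or_, lo, hi = est.odds_ratio()
    assert or_ == pytest.approx(np.exp(0.2))
    assert lo < or_ < hi
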