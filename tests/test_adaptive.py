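import numpy as np
import pytest

from sgrn import InvalidInputError
from sgrn.adaptive import adaptive_lasso_fit_gene, make_weights

from .conftest import tiny_instance
from .oracles import solve_penalized_ls


class TestMakeWeights:
    def test_unit_estimate_gives_unit_weight(self):
        for alpha in (0.0, 0.5, 1.0, 3.0):
            w = make_weights(np.array([1.0]), np.array([1.0]), alpha, alpha)
            assert w.w_b[0] == 1.0 and w.w_f[0] == 1.0

    def test_zero_exponent_special_case(self):
        # alpha = beta = 0: unit weight where nonzero, infinite where zero
        w = make_weights(np.array([0.7, 0.0]), np.array([0.3, 0.0]), 0.0, 0.0)
        np.testing.assert_array_equal(w.w_b, [1.0, np.inf])
        np.testing.assert_array_equal(w.w_f, [1.0, np.inf])

    def test_inverse_magnitude_weighting(self):
        w = make_weights(np.array([0.5]), np.array([0.25]), 1.0, 0.5)
        assert w.w_b[0] == pytest.approx(2.0)
        assert w.w_f[0] == pytest.approx(2.0)  # 0.25^-0.5

    def test_negative_exponent_rejected(self):
        with pytest.raises(InvalidInputError):
            make_weights(np.zeros(2), np.zeros(2), -1.0, 0.5)


class TestAdaptiveLassoFit:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_convex_oracle(self, seed):
        """Joint CD attains the weighted-ell1 optimum (finite weights)."""
        Yc, Xc = tiny_instance(seed, m_g=4, m_s=4, n=25)
        rng = np.random.default_rng(seed)
        b_hat = rng.uniform(0.3, 1.0, 4) * rng.choice([-1, 1], 4)
        f_hat = rng.uniform(0.3, 1.0, 4) * rng.choice([-1, 1], 4)
        i = seed % 4
        b_hat[i] = 0.0  # own-gene slot never carries an estimate
        w = make_weights(b_hat, f_hat, alpha=1.0, beta=0.5)
        lam1, lam2 = 0.6, 0.4
        b, f, sol = adaptive_lasso_fit_gene(i, Yc, Xc, w, lam1, lam2, tol=1e-10)
        D = np.vstack([np.delete(Yc, i, axis=0), Xc])
        l1_pen = np.concatenate([lam1 * np.delete(w.w_b, i), lam2 * w.w_f])
        _, obj_oracle = solve_penalized_ls(D, Yc[i], l1=l1_pen)
        assert abs(sol.objective - obj_oracle) < 1e-6
        assert b[i] == 0.0

    def test_dead_zone_zeroes_coordinate(self):
        # thresholds larger than any gradient magnitude leave every
        # coordinate in the soft-threshold dead zone
        Yc, Xc = tiny_instance(5, m_g=4, m_s=4, n=25)
        w = make_weights(np.ones(4), np.ones(4), 0.0, 0.0)
        b, f, _ = adaptive_lasso_fit_gene(1, Yc, Xc, w, 1e8, 1e8)
        assert np.all(b == 0.0) and np.all(f == 0.0)

    def test_infinite_f_weights_freeze_f(self):
        Yc, Xc = tiny_instance(6, m_g=4, m_s=4, n=25)
        w = make_weights(np.ones(4), np.zeros(4), 0.0, 0.0)  # f frozen
        b, f, sol = adaptive_lasso_fit_gene(0, Yc, Xc, w, 0.1, 0.1)
        assert np.all(f == 0.0)
        # reduces to a lasso on the gene block alone
        D = np.delete(Yc, 0, axis=0)
        _, obj_oracle = solve_penalized_ls(D, Yc[0], l1=np.full(3, 0.1))
        assert abs(sol.objective - obj_oracle) < 1e-6

    def test_unit_weights_reduce_to_plain_lasso(self):
        """With w = 1 and a shared lambda the solution is the ordinary lasso
        on the stacked design — cross-checked against scikit-learn."""
        from sklearn.linear_model import Lasso

        Yc, Xc = tiny_instance(7, m_g=4, m_s=4, n=30)
        i, lam = 2, 0.8
        w = make_weights(np.ones(4), np.ones(4), 0.0, 0.0)
        b, f, _ = adaptive_lasso_fit_gene(i, Yc, Xc, w, lam, lam, tol=1e-12)
        D = np.vstack([np.delete(Yc, i, axis=0), Xc])
        n = D.shape[1]
        sk = Lasso(alpha=lam / (2 * n), fit_intercept=False, tol=1e-14, max_iter=100000)
        sk.fit(D.T, Yc[i])
        theta = np.concatenate([np.delete(b, i), f])
        np.testing.assert_allclose(theta, sk.coef_, atol=1e-6)

    def test_objective_non_increasing_per_sweep(self):
        Yc, Xc = tiny_instance(8, m_g=5, m_s=5, n=30)
        w = make_weights(np.ones(5), np.ones(5), 0.0, 0.0)
        _, _, sol = adaptive_lasso_fit_gene(0, Yc, Xc, w, 0.3, 0.3,
                                            record_objective=True)
        assert np.all(np.diff(sol.objective_history) <= 1e-10)

    def test_support_within_finite_weights(self):
        Yc, Xc = tiny_instance(9, m_g=5, m_s=5, n=30)
        rng = np.random.default_rng(9)
        b_hat = np.where(rng.random(5) < 0.5, rng.uniform(0.3, 1, 5), 0.0)
        f_hat = np.where(rng.random(5) < 0.5, rng.uniform(0.3, 1, 5), 0.0)
        w = make_weights(b_hat, f_hat, 1.0, 0.5)
        b, f, _ = adaptive_lasso_fit_gene(1, Yc, Xc, w, 0.01, 0.01)
        assert np.all(b[~np.isfinite(w.w_b)] == 0.0)
        assert np.all(f[~np.isfinite(w.w_f)] == 0.0)
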