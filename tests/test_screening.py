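import numpy as np
import pytest

from sgrn import InvalidInputError, SimulationConfig, simulate_dataset
from sgrn.screening import (
    CandidateEqtls,
    elastic_net_fit_gene,
    lasso_path_eqtl,
    ridge_cv,
    ridge_fit_gene,
    truncate_candidates,
)

from .conftest import tiny_instance
from .oracles import solve_penalized_ls


def _stack(i, Yc, Xc):
    return np.vstack([np.delete(Yc, i, axis=0), Xc])


class TestRidge:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_normal_equation_oracle(self, seed):
        """The two-stage closed form equals the joint ridge minimizer."""
        Yc, Xc = tiny_instance(seed, m_g=3, m_s=3, n=20)
        lam1 = lam2 = 0.1
        for i in range(3):
            b, f = ridge_fit_gene(i, Yc, Xc, lam1, lam2)
            D = _stack(i, Yc, Xc)
            pen = np.concatenate([np.full(2, lam1), np.full(3, lam2)])
            theta = np.linalg.solve(D @ D.T + np.diag(pen), D @ Yc[i])
            np.testing.assert_allclose(np.delete(b, i), theta[:2], atol=1e-8)
            np.testing.assert_allclose(f, theta[2:], atol=1e-8)

    def test_infinite_penalty_shrinks_everything(self):
        Yc, Xc = tiny_instance(3, m_g=4, m_s=4, n=30)
        b, f = ridge_fit_gene(0, Yc, Xc, 1e8, 1e8)
        assert max(np.abs(b).max(), np.abs(f).max()) < 1e-3

    def test_vanishing_penalty_approaches_ols(self):
        Yc, Xc = tiny_instance(4, m_g=3, m_s=3, n=40)
        i = 1
        b, f = ridge_fit_gene(i, Yc, Xc, 1e-10, 1e-10)
        D = _stack(i, Yc, Xc)
        theta, *_ = np.linalg.lstsq(D.T, Yc[i], rcond=None)
        np.testing.assert_allclose(np.delete(b, i), theta[:2], atol=1e-5)
        np.testing.assert_allclose(f, theta[2:], atol=1e-5)

    def test_own_gene_excluded(self):
        Yc, Xc = tiny_instance(5, m_g=4, m_s=4, n=25)
        for i in range(4):
            b, _ = ridge_fit_gene(i, Yc, Xc, 1.0, 1.0)
            assert b[i] == 0.0

    def test_cv_single_point_grid(self, rng):
        Yc, Xc = tiny_instance(6, m_g=3, m_s=3, n=20)
        lam1, lam2 = ridge_cv(Yc, Xc, np.array([0.7]), k_folds=3, rng=rng)
        assert np.all(lam1 == 0.7) and np.all(lam2 == 0.7)

    def test_cv_prefers_weak_penalty_under_strong_signal(self, rng):
        ds = simulate_dataset(SimulationConfig(n_genes=6, n_samples=120,
                                               edges_per_gene=1.0, seed=8))
        lam1, _ = ridge_cv(ds.Y.centered, ds.X.centered,
                           np.array([1e-3, 1e3]), k_folds=5, rng=rng)
        assert np.all(lam1 == 1e-3)

    def test_cv_empty_grid_rejected(self, rng):
        Yc, Xc = tiny_instance(0, m_g=3, m_s=3, n=20)
        with pytest.raises(InvalidInputError):
            ridge_cv(Yc, Xc, np.array([]), k_folds=3, rng=rng)


class TestElasticNet:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_convex_oracle(self, seed):
        """CD on the profiled problem attains the joint elastic-net optimum."""
        Yc, Xc = tiny_instance(seed, m_g=4, m_s=4, n=25)
        lam1, lam2 = 0.5, 0.8
        for i in range(4):
            b, f, sol = elastic_net_fit_gene(i, Yc, Xc, lam1, lam2, tol=1e-10)
            D = _stack(i, Yc, Xc)
            ridge_pen = np.concatenate([np.full(3, lam1), np.zeros(4)])
            l1_pen = np.concatenate([np.zeros(3), np.full(4, lam2)])
            _, obj_oracle = solve_penalized_ls(D, Yc[i], ridge=ridge_pen, l1=l1_pen)
            # full objective of the CD solution, evaluated directly
            theta = np.concatenate([np.delete(b, i), f])
            resid = Yc[i] - theta @ D
            obj_cd = resid @ resid + lam1 * np.sum(np.delete(b, i) ** 2) \
                + lam2 * np.abs(f).sum()
            assert abs(obj_cd - obj_oracle) < 1e-6

    def test_large_lambda2_zeroes_f(self):
        Yc, Xc = tiny_instance(9, m_g=4, m_s=4, n=25)
        _, f, _ = elastic_net_fit_gene(0, Yc, Xc, 0.5, 1e6)
        assert np.all(f == 0.0)

    def test_objective_non_increasing_per_sweep(self):
        Yc, Xc = tiny_instance(10, m_g=5, m_s=5, n=30)
        _, _, sol = elastic_net_fit_gene(0, Yc, Xc, 0.5, 0.2, record_objective=True)
        assert np.all(np.diff(sol.objective_history) <= 1e-10)

    def test_support_shrinks_with_penalty(self):
        Yc, Xc = tiny_instance(11, m_g=5, m_s=5, n=40)
        supports = []
        for lam2 in (0.1, 1.0, 10.0, 100.0):
            _, f, _ = elastic_net_fit_gene(1, Yc, Xc, 0.5, lam2)
            supports.append(set(np.flatnonzero(np.abs(f) > 1e-8)))
        for stronger, weaker in zip(supports[1:], supports):
            assert stronger <= weaker

    def test_b_ii_zero(self):
        Yc, Xc = tiny_instance(12, m_g=4, m_s=4, n=25)
        for i in range(4):
            b, _, _ = elastic_net_fit_gene(i, Yc, Xc, 0.5, 0.5)
            assert b[i] == 0.0


class TestLassoPathEqtl:
    def test_single_candidate_short_circuits(self, small_dataset):
        Yc, Xc = small_dataset.Y.centered, small_dataset.X.centered
        F = np.zeros((10, 10))
        F[2, 7] = 0.4
        snp, lam, fallback = lasso_path_eqtl(2, Yc, Xc, CandidateEqtls(F))
        assert snp == 7 and not fallback

    def test_empty_candidates_flagged(self, small_dataset):
        Yc, Xc = small_dataset.Y.centered, small_dataset.X.centered
        snp, lam, fallback = lasso_path_eqtl(0, Yc, Xc, CandidateEqtls(np.zeros((10, 10))))
        assert snp is None and fallback

    def test_recovers_true_eqtl_with_weak_confounders(self, sparse_dataset):
        """On sparse synthetic data the first-entering SNP is the true one."""
        ds = sparse_dataset
        Yc, Xc = ds.Y.centered, ds.X.centered
        # candidate set = truth + two decoys for every gene
        F = np.zeros((10, 10))
        for i in range(10):
            F[i, i] = ds.model.F.values[i, i]
            F[i, (i + 3) % 10] = 0.05
            F[i, (i + 5) % 10] = 0.03
        hits = sum(
            lasso_path_eqtl(i, Yc, Xc, CandidateEqtls(F))[0] == i for i in range(10)
        )
        assert hits >= 9

    def test_result_always_from_candidate_set(self, small_dataset):
        Yc, Xc = small_dataset.Y.centered, small_dataset.X.centered
        rng = np.random.default_rng(0)
        F = np.zeros((10, 10))
        for i in range(10):
            F[i, rng.choice(10, size=3, replace=False)] = rng.normal(size=3)
        cand = truncate_candidates(F)
        for i in range(10):
            snp, _, fallback = lasso_path_eqtl(i, Yc, Xc, cand)
            assert snp in set(cand.candidates(i))


class TestTruncation:
    def test_keeps_top_k_by_magnitude(self):
        F = np.array([[0.1, -0.9, 0.5, 0.2, -0.3, 0.05, 0.0, 0.0]])
        cand = truncate_candidates(F, top_k=3)
        assert set(cand.candidates(0)) == {1, 2, 4}
        np.testing.assert_array_equal(cand.candidates(0), [1, 2, 4])

    def test_default_top_k_is_five(self):
        F = np.array([np.linspace(0.1, 0.8, 8)])
        cand = truncate_candidates(F)
        assert len(cand.candidates(0)) == 5
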