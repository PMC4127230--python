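import numpy as np
import pytest

from sgrn import (
    EqtlMatrix,
    GeneAdjacency,
    GenotypeMatrix,
    InvalidInputError,
    SemModel,
    SimulationConfig,
    simulate_dataset,
)
from sgrn.simulate import generate_expression, sample_genotypes, sample_network


class TestNetworkSampling:
    def test_acyclic_by_construction(self):
        for seed in range(5):
            ds = simulate_dataset(SimulationConfig(n_genes=12, n_samples=10,
                                                   edges_per_gene=2.0, seed=seed))
            order = ds.topological_order
            permuted = ds.model.B.values[np.ix_(order, order)]
            assert np.allclose(np.triu(permuted), 0.0), "edges must respect the order"

    def test_coefficient_law_bounds(self):
        cfg = SimulationConfig(n_genes=15, n_samples=10, edges_per_gene=3.0, seed=3)
        model, _ = sample_network(cfg, np.random.default_rng(3))
        nz = model.B.values[model.B.values != 0]
        assert nz.size > 0
        assert np.all((np.abs(nz) >= 0.5) & (np.abs(nz) <= 1.0))
        f_diag = np.diag(model.F.values)
        assert np.all((np.abs(f_diag) >= 0.5) & (np.abs(f_diag) <= 1.0))

    def test_expected_edge_count(self):
        cfg = SimulationConfig(n_genes=10, n_samples=10, edges_per_gene=1.0, seed=0)
        rng = np.random.default_rng(0)
        counts = [sample_network(cfg, rng)[0].B.n_edges for _ in range(300)]
        # mean of 300 draws of Binomial(45, 10/45); se ~ 0.17
        assert abs(np.mean(counts) - 10.0) < 0.7

    def test_f_diagonal_full_support(self):
        cfg = SimulationConfig(n_genes=8, n_samples=10, edges_per_gene=1.0, seed=5)
        model, _ = sample_network(cfg, np.random.default_rng(5))
        f = model.F.values
        assert np.all(np.abs(np.diag(f)) >= 0.5)
        assert np.count_nonzero(f - np.diag(np.diag(f))) == 0

    def test_infeasible_edge_budget_rejected(self):
        with pytest.raises(InvalidInputError, match="edge budget"):
            SimulationConfig(n_genes=4, n_samples=10, edges_per_gene=3.0)


class TestGenotypes:
    def test_frequencies_and_codes(self):
        cfg = SimulationConfig(n_genes=100, n_samples=1000, edges_per_gene=1.0, seed=9)
        g = sample_genotypes(cfg, np.random.default_rng(9))
        vals = g.values.ravel()  # 10^5 draws
        assert set(np.unique(vals)) <= {1, 2, 3}
        freqs = [(vals == v).mean() for v in (1, 2, 3)]
        np.testing.assert_allclose(freqs, [0.25, 0.5, 0.25], atol=0.01)


class TestExpression:
    def test_identity_reduction(self):
        # no regulation, unit eQTL effects, no noise: expression equals genotype
        model = SemModel(B=GeneAdjacency(np.zeros((3, 3))),
                         F=EqtlMatrix(np.eye(3)), noise_variance=0.0)
        X = GenotypeMatrix(np.array([[1, 2, 3], [3, 1, 2], [2, 2, 1]]))
        Y, E = generate_expression(model, X, np.random.default_rng(0))
        np.testing.assert_allclose(Y.values, X.values.astype(float))
        assert np.all(E == 0.0)

    def test_two_gene_chain_hand_solved(self):
        # y1 = x1, y2 = y1 + x2  =>  x = (1, 1) gives y = (1, 2)
        b = np.zeros((2, 2))
        b[1, 0] = 1.0
        model = SemModel(B=GeneAdjacency(b), F=EqtlMatrix(np.eye(2)), noise_variance=0.0)
        X = GenotypeMatrix(np.array([[1, 1], [1, 1]]))
        Y, _ = generate_expression(model, X, np.random.default_rng(0))
        np.testing.assert_allclose(Y.values[:, 0], [1.0, 2.0])

    def test_residual_recovers_stored_noise(self, small_dataset):
        ds = small_dataset
        resid = (np.eye(ds.model.n_genes) - ds.model.B.values) @ ds.Y.values \
            - ds.model.F.values @ ds.X.values
        np.testing.assert_allclose(resid, ds.noise, atol=1e-10)

    def test_noise_variance_scale(self):
        ds = simulate_dataset(SimulationConfig(n_genes=10, n_samples=500,
                                               edges_per_gene=1.0, seed=21))
        resid = (np.eye(10) - ds.model.B.values) @ ds.Y.values \
            - ds.model.F.values @ ds.X.values
        assert 0.008 <= resid.var() <= 0.012  # nominal 0.01 +/- 20%


class TestReproducibility:
    def test_same_seed_bitwise_identical(self):
        cfg = SimulationConfig(n_genes=8, n_samples=50, edges_per_gene=2.0, seed=13)
        a, b = simulate_dataset(cfg), simulate_dataset(cfg)
        np.testing.assert_array_equal(a.Y.values, b.Y.values)
        np.testing.assert_array_equal(a.X.values, b.X.values)
        np.testing.assert_array_equal(a.model.B.values, b.model.B.values)
        np.testing.assert_array_equal(a.model.F.values, b.model.F.values)

    def test_different_seeds_differ(self):
        a = simulate_dataset(SimulationConfig(n_genes=8, n_samples=50, seed=1))
        b = simulate_dataset(SimulationConfig(n_genes=8, n_samples=50, seed=2))
        assert not np.array_equal(a.Y.values, b.Y.values)
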