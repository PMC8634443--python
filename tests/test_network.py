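"""KDE, KL similarity and sparsity binarization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphnet.images import RegionalSamples
from morphnet.network import (DensityEstimate, SimilarityMatrix,
                              binarize_at_sparsity, build_similarity_matrix,
                              estimate_density, kl_similarity, sparsity_grid,
                              sparsity_series, symmetric_kl)


def _gauss_density(grid, mu, sigma):
    d = np.exp(-0.5 * ((grid - mu) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
    return DensityEstimate(grid=grid, density=d, bandwidth=sigma)


class TestDensityEstimate:
    def test_moments_recover_generating_distribution(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.5, 0.1, 10_000)
        d = estimate_density(x)
        assert d.mean() == pytest.approx(0.5, rel=0.02)
        assert d.variance() == pytest.approx(0.01, rel=0.02)

    def test_density_positive_and_normalized(self):
        x = np.random.default_rng(1).uniform(0.2, 0.4, 50)
        d = estimate_density(x)
        assert np.all(d.density > 0)
        assert np.trapezoid(d.density, d.grid) == pytest.approx(1.0, abs=1e-3)

    def test_duplicating_samples_changes_nothing_at_fixed_bandwidth(self):
        x = np.random.default_rng(2).normal(0.5, 0.05, 200)
        d1 = estimate_density(x, bandwidth=0.02, support=(0.3, 0.7))
        d2 = estimate_density(np.concatenate([x, x]), bandwidth=0.02,
                              support=(0.3, 0.7))
        assert np.abs(d1.density - d2.density).max() < 1e-6

    def test_degenerate_samples_error_mentions_jitter(self):
        with pytest.raises(ValueError, match="jitter"):
            estimate_density(np.full(10, 0.5))

    def test_grid_validation(self):
        with pytest.raises(ValueError, match="uniform"):
            DensityEstimate(grid=np.array([0.0, 1.0, 3.0]),
                            density=np.ones(3), bandwidth=0.1)


class TestKLSimilarity:
    def test_identical_distributions_similarity_one(self):
        g = np.linspace(0, 1, 256)
        p = _gauss_density(g, 0.5, 0.1)
        assert kl_similarity(p, p) == 1.0

    def test_gaussian_closed_form(self):
        """Symmetric KL of two equal-variance Gaussians is (mu1-mu2)^2/sigma^2."""
        g = np.linspace(0.0, 1.0, 4096)
        p = _gauss_density(g, 0.4, 0.05)
        q = _gauss_density(g, 0.6, 0.05)
        assert symmetric_kl(p, q) == pytest.approx(16.0, rel=0.02)
        assert kl_similarity(p, q) == pytest.approx(np.exp(-16.0), rel=0.05)

    def test_symmetry(self):
        g = np.linspace(0, 1, 512)
        p = _gauss_density(g, 0.3, 0.07)
        q = _gauss_density(g, 0.65, 0.12)
        assert kl_similarity(p, q) == kl_similarity(q, p)

    def test_grid_mismatch_rejected(self):
        p = _gauss_density(np.linspace(0, 1, 128), 0.5, 0.1)
        q = _gauss_density(np.linspace(0, 2, 128), 0.5, 0.1)
        with pytest.raises(ValueError, match="grid"):
            kl_similarity(p, q)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_discrete_kl_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        g = np.linspace(0, 1, 128)
        mu1, mu2 = rng.uniform(0.2, 0.8, 2)
        s1, s2 = rng.uniform(0.03, 0.2, 2)
        assert symmetric_kl(_gauss_density(g, mu1, s1),
                            _gauss_density(g, mu2, s2)) >= -1e-12

    def test_similarity_decreases_with_separation(self):
        """Pulling the generating distributions apart lowers the similarity."""
        g = np.linspace(-1, 2, 1024)
        base = _gauss_density(g, 0.5, 0.1)
        sims = [kl_similarity(base, _gauss_density(g, 0.5 + delta, 0.1))
                for delta in (0.0, 0.05, 0.1, 0.2, 0.4)]
        assert all(a > b for a, b in zip(sims, sims[1:]))


class TestSimilarityMatrix:
    def test_identical_regions_give_unit_matrix(self):
        x = np.random.default_rng(3).normal(0.5, 0.1, 80)
        rs = RegionalSamples("s", {r: x.copy() for r in range(1, 6)})
        sim = build_similarity_matrix(rs)
        np.testing.assert_allclose(sim.values, 1.0)

    def test_region_order_equivariance(self):
        rng = np.random.default_rng(4)
        data = {r: rng.normal(0.3 + 0.1 * r, 0.05, 60) for r in range(1, 6)}
        rs = RegionalSamples("s", data)
        ids = [1, 2, 3, 4, 5]
        sim = build_similarity_matrix(rs, ids)
        perm = [3, 1, 5, 2, 4]
        sim_p = build_similarity_matrix(rs, perm)
        inv = [perm.index(r) for r in ids]
        np.testing.assert_allclose(sim_p.values[np.ix_(inv, inv)], sim.values,
                                   atol=1e-12)

    def test_determinism(self):
        rng = np.random.default_rng(5)
        data = {r: rng.normal(0.5, 0.1, 40) for r in range(1, 5)}
        a = build_similarity_matrix(RegionalSamples("s", data))
        b = build_similarity_matrix(RegionalSamples("s", data))
        np.testing.assert_array_equal(a.values, b.values)

    def test_degenerate_region_named_in_error(self):
        data = {1: np.random.default_rng(6).normal(0.5, 0.1, 30),
                2: np.full(30, 0.4)}
        with pytest.raises(ValueError, match="2"):
            build_similarity_matrix(RegionalSamples("s", data))


class TestBinarization:
    @pytest.fixture
    def sim90(self):
        rng = np.random.default_rng(7)
        w = rng.uniform(0.01, 0.99, (90, 90))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        return SimilarityMatrix("s", w, list(range(1, 91)))

    def test_edge_count_at_sparsity(self, sim90):
        net = binarize_at_sparsity(sim90, 0.05)
        assert net.n_edges == 200  # floor(0.05 * 4005)

    def test_near_one_sparsity_nearly_complete_graph(self, sim90):
        # K = floor(s * 4005) keeps all but one pair as s -> 1
        net = binarize_at_sparsity(sim90, 0.9999)
        assert net.n_edges == 4004
        assert not np.any(np.diagonal(net.adjacency))

    def test_nested_edge_sets(self, sim90):
        n1 = binarize_at_sparsity(sim90, 0.05)
        n2 = binarize_at_sparsity(sim90, 0.07)
        assert np.all(n2.adjacency[n1.adjacency])

    def test_tie_break_deterministic(self):
        w = np.full((5, 5), 0.5)
        np.fill_diagonal(w, 1.0)
        sim = SimilarityMatrix("s", w, list(range(1, 6)))
        net = binarize_at_sparsity(sim, 0.3)  # floor(0.3*10) = 3 edges
        iu, ju = np.nonzero(np.triu(net.adjacency, 1))
        assert list(zip(iu.tolist(), ju.tolist())) == [(0, 1), (0, 2), (0, 3)]

    def test_invalid_sparsity(self, sim90):
        for s in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                binarize_at_sparsity(sim90, s)

    def test_series_has_18_levels_and_monotone_edges(self, sim90):
        nets = sparsity_series(sim90)
        assert len(nets) == 18
        counts = [n.n_edges for n in nets]
        assert counts == sorted(counts) and len(set(counts)) == 18
        np.testing.assert_allclose([n.sparsity for n in nets],
                                   np.arange(0.05, 0.40, 0.02))

    def test_single_level_series(self, sim90):
        assert len(sparsity_series(sim90, 0.1, 0.1, 0.02)) == 1

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sparsity_grid(0.3, 0.1, 0.02)
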