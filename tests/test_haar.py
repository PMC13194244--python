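"""Haar-like basis construction, the sparse transform, and sparsity bounds."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phylohaar import (
    EnsembleConfig,
    build_basis,
    covariance_dense,
    load_newick,
    sample_tree,
    sparsity_bound,
    sparsity_stats,
    transform,
)
from conftest import random_trees


class TestBasis:
    def test_balanced_four_leaf_wavelets(self, balanced4):
        phi = build_basis(balanced4).dense()
        cols = {tuple(np.round(phi[:, k], 6)) for k in range(4)}
        s2 = 1 / np.sqrt(2)
        assert (0.5, 0.5, 0.5, 0.5) in cols
        assert (0.5, 0.5, -0.5, -0.5) in cols
        assert (round(s2, 6), round(-s2, 6), 0.0, 0.0) in cols
        assert (0.0, 0.0, round(s2, 6), round(-s2, 6)) in cols

    def test_caterpillar_top_wavelet(self, caterpillar3):
        b = build_basis(caterpillar3)
        k = b.wavelet_index(caterpillar3.top)
        phi = b.dense()[:, k]
        assert np.allclose(phi, [np.sqrt(2 / 3), -1 / np.sqrt(6), -1 / np.sqrt(6)])

    def test_constant_projects_only_on_root(self):
        for t in random_trees(10, seed=11):
            b = build_basis(t)
            coords = b.coordinates(np.ones(t.n_leaves))
            assert abs(coords[0] - np.sqrt(t.n_leaves)) < 1e-12
            assert np.all(np.abs(coords[1:]) < 1e-12)

    def test_orthonormal_and_zero_sum(self):
        rng = np.random.default_rng(2)
        for n in (2, 17, 128, 256):
            t = sample_tree(EnsembleConfig(n=n), rng=rng)
            phi = build_basis(t).dense()
            assert np.abs(phi.T @ phi - np.eye(n)).max() < 1e-12
            assert np.all(np.abs(phi[:, 1:].sum(axis=0)) < 1e-12)

    def test_coordinates_match_dense_dot_products(self):
        rng = np.random.default_rng(4)
        t = sample_tree(EnsembleConfig(n=33), rng=rng)
        b = build_basis(t)
        f = rng.normal(size=33)
        assert np.allclose(b.coordinates(f), b.dense().T @ f, atol=1e-12)


class TestCovariance:
    def test_balanced_hand_matrix(self, balanced4):
        expected = np.array(
            [[3, 2, 1, 1], [2, 3, 1, 1], [1, 1, 3, 2], [1, 1, 2, 3]], dtype=float
        )
        assert np.allclose(covariance_dense(balanced4), expected)

    def test_single_leaf(self):
        assert np.allclose(covariance_dense(load_newick("A:2.5;")), [[2.5]])

    def test_positive_semidefinite(self):
        for t in random_trees(10, n_max=32, seed=13):
            eig = np.linalg.eigvalsh(covariance_dense(t))
            assert eig.min() > -1e-10

    def test_cap(self):
        t = sample_tree(EnsembleConfig(n=20, seed=0))
        with pytest.raises(ValueError, match="transform"):
            covariance_dense(t, cap=10)


class TestTransform:
    def test_balanced_diagonal(self, balanced4):
        s = transform(balanced4)
        assert s.diagonal[0] == pytest.approx(7.0)
        assert sorted(np.round(s.diagonal[1:], 10)) == [1.0, 1.0, 3.0]
        assert np.abs(s.values).max() == pytest.approx(0.0, abs=1e-14)

    def test_caterpillar_lambda_and_offdiagonal(self, caterpillar3):
        s = transform(caterpillar3)
        assert s.diagonal[0] == pytest.approx(16 / 3)
        assert sorted(np.round(s.diagonal[1:], 10)) == pytest.approx([1.0, 5 / 3])
        nonzero = s.values[np.abs(s.values) > 1e-12]
        assert len(nonzero) == 1
        assert nonzero[0] == pytest.approx(-2 * np.sqrt(2) / 3)

    def test_planted_length_shifts_only_root_lambda(self):
        t0 = load_newick("((A:1,B:1):1,(C:1,D:1):1):0;")
        t1 = load_newick("((A:1,B:1):1,(C:1,D:1):1):2.5;")
        s0, s1 = transform(t0), transform(t1)
        assert s1.diagonal[0] - s0.diagonal[0] == pytest.approx(2.5 * 4)
        assert np.allclose(s1.diagonal[1:], s0.diagonal[1:])
        assert np.allclose(s1.values, s0.values)

    def test_matches_dense_oracle(self):
        worst = 0.0
        for t in random_trees(60, seed=17):
            s = transform(t)
            phi = s.basis.dense()
            dense = phi.T @ covariance_dense(t) @ phi
            worst = max(worst, np.abs(dense - s.to_dense()).max())
        assert worst < 1e-10

    def test_trace_conservation_and_nonnegative_diagonal(self):
        for t in random_trees(30, seed=19):
            s = transform(t)
            trace_c = t.weighted_depths()[t.leaf_order].sum()
            assert abs(s.trace() - trace_c) < 1e-10 * max(1.0, trace_c)
            assert np.all(s.diagonal >= -1e-12)

    def test_structural_pair_count_bounded_by_depth_sum(self):
        for t in random_trees(20, seed=23):
            s = transform(t)
            depth_sum = t.depths("planted")[t.interior_nodes].sum()
            assert s.n_structural_pairs <= 2 * depth_sum


class TestSparsity:
    def test_balanced_stats(self, balanced4):
        s = transform(balanced4)
        assert sparsity_stats(s, "structural")["xi"] == pytest.approx(2 / 12)
        assert sparsity_stats(s, "numerical")["xi"] == pytest.approx(1.0)

    def test_caterpillar_numerical(self, caterpillar3):
        s = transform(caterpillar3)
        assert sparsity_stats(s, "numerical")["xi"] == pytest.approx(4 / 6)

    def test_diagonal_transform_is_fully_sparse(self):
        s = transform(load_newick("(A:1,B:1):1;"))
        assert sparsity_stats(s, "numerical")["xi"] == 1.0

    def test_bound_examples(self, balanced4, caterpillar4):
        assert sparsity_bound(balanced4) == pytest.approx(0.875)
        stats = sparsity_stats(transform(balanced4), "structural")
        assert stats["nonzero_offdiag_fraction"] == pytest.approx(10 / 12)
        assert stats["nonzero_offdiag_fraction"] <= 0.875
        assert sparsity_bound(caterpillar4) == pytest.approx(1.0)

    def test_bound_holds_on_random_trees(self):
        for t in random_trees(40, seed=29):
            s = transform(t)
            observed = sparsity_stats(s, "structural")["nonzero_offdiag_fraction"]
            assert observed <= sparsity_bound(t) + 1e-12

    def test_sparsity_increases_with_tree_size(self):
        """Mean structural vanishing fraction grows with n for critical
        beta-splitting trees (the pseudo-diagonalization-in-probability
        behavior)."""
        rng = np.random.default_rng(31)
        means = []
        for n in (64, 256, 1024, 4096):
            xs = [
                sparsity_stats(transform(sample_tree(EnsembleConfig(n=n), rng=rng)))["xi"]
                for _ in range(30)
            ]
            means.append(np.mean(xs))
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_invalid_args(self, balanced4):
        s = transform(balanced4)
        with pytest.raises(ValueError):
            sparsity_stats(s, "numerical", tol=-1)
        with pytest.raises(ValueError):
            sparsity_stats(s, "bogus")


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(2, 48))
def test_transform_equals_dense_property(seed, n):
    """Property form of the oracle equivalence over seeded random trees."""
    rng = np.random.default_rng(seed)
    law = "critical_beta" if seed % 2 else "uniform"
    t = sample_tree(EnsembleConfig(n=n, law=law, edge_lengths="exponential"), rng=rng)
    s = transform(t)
    phi = s.basis.dense()
    assert np.abs(phi.T @ covariance_dense(t) @ phi - s.to_dense()).max() < 1e-10
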