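import math

import numpy as np
import pytest
from scipy import sparse

from sigbin.embedding import (
    TsneParams,
    bh_gradient,
    conditional_affinities,
    exact_gradient,
    joint_affinities,
    kl_divergence,
    run_tsne,
    symmetrize,
)
from sigbin.synthetic import knn_label_purity


def double_loop_gradient(P: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Literal transcription of the t-SNE gradient, pair by pair."""
    n = len(Y)
    num = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                d2 = np.sum((Y[i] - Y[j]) ** 2)
                num[i, j] = 1.0 / (1.0 + d2)
    Z = num.sum()
    grad = np.zeros_like(Y)
    for i in range(n):
        for j in range(n):
            if i != j:
                q = num[i, j] / Z
                grad[i] += 4.0 * (P[i, j] - q) * num[i, j] * (Y[i] - Y[j])
    return grad


def double_loop_kl(P: np.ndarray, Y: np.ndarray) -> float:
    n = len(Y)
    num = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                num[i, j] = 1.0 / (1.0 + np.sum((Y[i] - Y[j]) ** 2))
    Z = num.sum()
    kl = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and P[i, j] > 0:
                kl += P[i, j] * math.log(P[i, j] / max(num[i, j] / Z, 1e-12))
    return kl


def two_cluster_data(rng, n_per=50, dim=10, sep=8.0):
    X = np.vstack(
        [rng.normal(0, 1, (n_per, dim)), rng.normal(sep, 1, (n_per, dim))]
    )
    labels = ["a"] * n_per + ["b"] * n_per
    return X, labels


class TestAffinities:
    def test_tetrahedron_uniform_conditionals(self):
        # four equidistant points force p_{j|i} = 1/3 at any bandwidth
        Y = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        )
        aff = conditional_affinities(Y, perplexity=3.0)
        P = aff.P.toarray()
        for i in range(4):
            row = np.delete(P[i], i)
            assert np.allclose(row, 1 / 3, atol=1e-9)
            assert P[i, i] == 0

    def test_perplexity_calibration(self, rng):
        X = rng.standard_normal((50, 10))
        perp = 10.0
        aff = conditional_affinities(X, perp)
        P = aff.P.toarray()
        for i in range(50):
            p = P[i][P[i] > 0]
            H = -(p * np.log2(p)).sum()
            assert abs(2**H - perp) <= 1e-4 * perp

    def test_neighbor_sets_match_brute_force(self, rng):
        X = rng.standard_normal((50, 10))
        aff = conditional_affinities(X, 10.0)
        k = 30
        D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        np.fill_diagonal(D, np.inf)
        P = aff.P.toarray()
        for i in range(50):
            expected = set(np.argsort(D[i], kind="stable")[:k])
            stored = set(np.flatnonzero(P[i]))
            assert stored == expected

    def test_perplexity_too_large_error(self, rng):
        with pytest.raises(ValueError):
            conditional_affinities(rng.standard_normal((5, 3)), perplexity=4.5)

    def test_duplicate_points_fall_back_to_uniform(self):
        X = np.zeros((6, 3))
        aff = conditional_affinities(X, 1.5)
        P = aff.P.toarray()
        row = P[0][P[0] > 0]
        assert np.allclose(row, row[0])


class TestSymmetrize:
    def test_sums_to_one_and_symmetric(self, rng):
        X = rng.standard_normal((30, 5))
        P = symmetrize(conditional_affinities(X, 5.0)).P
        dense = P.toarray()
        assert abs(dense.sum() - 1.0) <= 1e-9
        assert (dense == dense.T).all()

    def test_symmetric_input_proportional_output(self):
        Y = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
        cond = conditional_affinities(Y, 3.0)
        joint = symmetrize(cond).P.toarray()
        ratio = joint[cond.P.toarray() > 0] / cond.P.toarray()[cond.P.toarray() > 0]
        assert np.allclose(ratio, ratio[0])

    def test_sparsity_pattern_is_knn_union(self, rng):
        X = rng.standard_normal((20, 4))
        cond = conditional_affinities(X, 3.0)
        joint = symmetrize(cond)
        C = cond.P.toarray() > 0
        assert ((joint.P.toarray() > 0) == (C | C.T)).all()


class TestGradients:
    def test_two_points_equal_and_opposite(self):
        P = sparse.csr_matrix(np.array([[0.0, 0.5], [0.5, 0.0]]))
        Y = np.array([[0.0, 0.0], [1.0, 0.5]])
        g = exact_gradient(P, Y)
        assert np.allclose(g[0], -g[1], atol=1e-12)

    def test_exact_matches_double_loop(self, rng):
        X = rng.standard_normal((40, 6))
        P = joint_affinities(X, 8.0)
        Y = rng.standard_normal((40, 2))
        g = exact_gradient(P, Y)
        g_ref = double_loop_gradient(P.P.toarray(), Y)
        assert np.abs(g - g_ref).max() < 1e-10

    def test_bh_theta_zero_equals_exact(self, rng):
        X = rng.standard_normal((80, 6))
        P = joint_affinities(X, 10.0)
        Y = rng.standard_normal((80, 2))
        assert np.abs(bh_gradient(P, Y, 0.0) - exact_gradient(P, Y)).max() < 1e-9

    def test_bh_error_decreases_with_theta(self, rng):
        X = rng.standard_normal((150, 6))
        P = joint_affinities(X, 15.0)
        Y = rng.standard_normal((150, 2)) * 3
        g_exact = exact_gradient(P, Y)
        errs = []
        for theta in (1.0, 0.5, 0.25, 0.1):
            g = bh_gradient(P, Y, theta)
            errs.append(np.linalg.norm(g - g_exact) / np.linalg.norm(g_exact))
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))
        assert errs[1] < 0.05  # theta = 0.5 within 5% relative Frobenius

    def test_quadtree_mass_and_center_conservation(self, rng):
        from sigbin._bh import _build_tree

        Y = rng.standard_normal((200, 2))
        child, half, cum_mass, com_sum, is_leaf, n_nodes = _build_tree(Y)
        assert cum_mass[0] == 200
        assert np.allclose(com_sum[0] / cum_mass[0], Y.mean(axis=0), atol=1e-12)
        leaf_mass = sum(
            cum_mass[i] for i in range(n_nodes) if is_leaf[i]
        )
        assert leaf_mass == 200


class TestKl:
    def test_matched_two_point_system_is_zero(self):
        # with a single pair, q_ij = 1/2 regardless of distance; choose p to match
        P = sparse.csr_matrix(np.array([[0.0, 0.5], [0.5, 0.0]]))
        Y = np.array([[0.0, 0.0], [3.0, 4.0]])
        assert kl_divergence(P, Y) == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative(self, rng):
        X = rng.standard_normal((30, 4))
        P = joint_affinities(X, 5.0)
        for _ in range(5):
            assert kl_divergence(P, rng.standard_normal((30, 2))) >= 0.0

    def test_matches_double_loop(self, rng):
        X = rng.standard_normal((50, 5))
        P = joint_affinities(X, 8.0)
        Y = rng.standard_normal((50, 2))
        assert kl_divergence(P, Y) == pytest.approx(
            double_loop_kl(P.P.toarray(), Y), abs=1e-10
        )


class TestRunTsne:
    def test_same_seed_bit_identical(self, rng):
        X = rng.standard_normal((60, 8))
        params = TsneParams(perplexity=8.0, n_iter=120, seed=42)
        a = run_tsne(X, params)
        b = run_tsne(X, params)
        assert (a.coords == b.coords).all()
        assert a.kl_trace == b.kl_trace

    def test_n_threads_does_not_change_result(self, rng):
        X = rng.standard_normal((40, 5))
        a = run_tsne(X, TsneParams(perplexity=6.0, n_iter=60, seed=1, n_threads=1))
        b = run_tsne(X, TsneParams(perplexity=6.0, n_iter=60, seed=1, n_threads=4))
        assert (a.coords == b.coords).all()

    def test_two_clusters_separate(self, rng):
        X, labels = two_cluster_data(rng)
        result = run_tsne(X, TsneParams(perplexity=10.0, seed=3))
        assert knn_label_purity(result.coords, labels, k=5) >= 0.95

    def test_kl_decreases_after_exaggeration(self, rng):
        X, _ = two_cluster_data(rng, n_per=40)
        for seed in range(3):
            result = run_tsne(X, TsneParams(perplexity=10.0, seed=seed))
            trace = dict(result.kl_trace)
            assert trace[1000] <= trace[300]

    def test_trace_recorded_every_50(self, rng):
        X = rng.standard_normal((30, 4))
        result = run_tsne(X, TsneParams(perplexity=5.0, n_iter=120, seed=0))
        assert [it for it, _ in result.kl_trace] == [50, 100, 120]

    def test_short_run_permutation_equivariance(self, rng):
        X = rng.standard_normal((40, 6))
        perm = rng.permutation(40)
        init = rng.standard_normal((40, 2)) * 1e-4
        params = TsneParams(perplexity=6.0, n_iter=10, seed=0)
        a = run_tsne(X, params, init=init)
        b = run_tsne(X[perm], params, init=init[perm])
        assert np.allclose(b.coords, a.coords[perm], atol=1e-8)

    def test_rejects_tiny_input(self, rng):
        with pytest.raises(ValueError):
            run_tsne(rng.standard_normal((3, 4)), TsneParams())
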