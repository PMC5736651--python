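"""Reconstruction weights and the NPE eigenproblem against independent
oracles (KKT solve, Rayleigh-quotient brute force)."""

import numpy as np
import pytest
import scipy.sparse as sp

from npembed import (DataError, NeighbourGraph, compute_reconstruction_weights,
                     fit_npe, transform_npe)
from npembed.npe import GRAM_EPS


def _graph_from_lists(lists, k=None):
    k = k or max(len(l) for l in lists)
    return NeighbourGraph([np.asarray(l) for l in lists],
                          [np.ones(len(l)) for l in lists], k, "product",
                          short_rows=np.zeros(len(lists), dtype=bool))


def _knn_graph(X, k):
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    lists = [np.argsort(d2[i], kind="stable")[:k] for i in range(len(X))]
    return _graph_from_lists(lists, k)


def kkt_weights(X, i, neighbours):
    """Independent constrained least-squares oracle: full KKT system in the
    difference-Gram formulation (not the solve-then-normalize route)."""
    Z = X[np.asarray(neighbours)] - X[i]
    C = Z @ Z.T
    k = len(neighbours)
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = 2 * C
    kkt[:k, k] = 1.0
    kkt[k, :k] = 1.0
    rhs = np.zeros(k + 1)
    rhs[k] = 1.0
    sol = np.linalg.solve(kkt, rhs)
    return sol[:k]


class TestReconstructionWeights:
    def test_midpoint_gets_half_half(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.5], [1.5, 0.75]])
        # subject 3 is exactly the midpoint of subjects 1 and 2
        g = _graph_from_lists([[1], [0], [0], [1, 2]])
        w = compute_reconstruction_weights(X, g)
        np.testing.assert_allclose(w.W[3].toarray().ravel()[[1, 2]],
                                   [0.5, 0.5], atol=1e-9)

    def test_single_neighbour_weight_exactly_one(self, rng):
        X = rng.normal(size=(5, 3))
        g = _graph_from_lists([[1], [2], [3], [4], [0]])
        w = compute_reconstruction_weights(X, g)
        for i in range(5):
            assert w.W[i].sum() == pytest.approx(1.0, abs=0)

    def test_rows_match_kkt_oracle(self):
        rng = np.random.default_rng(77)
        X = rng.normal(size=(12, 4))
        g = _knn_graph(X, k=3)
        w = compute_reconstruction_weights(X, g)
        for i in range(12):
            expected = kkt_weights(X, i, g.neighbours[i])
            got = w.W[i].toarray().ravel()[g.neighbours[i]]
            np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_rows_sum_to_one_and_support_on_graph(self, rng):
        X = rng.normal(size=(15, 5))
        g = _knn_graph(X, k=4)
        w = compute_reconstruction_weights(X, g)
        np.testing.assert_allclose(np.asarray(w.W.sum(axis=1)).ravel(), 1.0,
                                   atol=1e-10)
        assert np.all(w.W.diagonal() == 0.0)
        ind = g.indicator()
        assert np.all(ind[w.W.toarray() != 0.0])

    def test_degenerate_gram_is_regularized(self):
        X = np.zeros((3, 2))  # all identical: Gram singular
        g = _graph_from_lists([[1, 2], [0, 2], [0, 1]])
        w = compute_reconstruction_weights(X, g)
        assert np.all(w.regularized)
        np.testing.assert_allclose(np.asarray(w.W.sum(axis=1)).ravel(), 1.0)

    def test_empty_neighbour_row_is_error(self, rng):
        g = _graph_from_lists([[1], []])
        with pytest.raises(DataError, match="empty"):
            compute_reconstruction_weights(rng.normal(size=(2, 2)), g)


class TestFitNpe:
    def test_duplicated_subjects_get_identical_embeddings(self, rng):
        X = rng.normal(size=(10, 4))
        X[5] = X[2]
        g = _knn_graph(X, k=3)
        w = compute_reconstruction_weights(X, g)
        model = fit_npe(X, w, d=2)
        np.testing.assert_allclose(model.embedding[5], model.embedding[2],
                                   atol=1e-8)

    def test_rayleigh_quotient_beats_random_directions(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 3))
        X = X - X.mean(axis=0)
        g = _knn_graph(X, k=4)
        w = compute_reconstruction_weights(X, g)
        model = fit_npe(X, w, d=1)
        IW = sp.identity(15) - w.W
        M = (IW.T @ IW).toarray()
        y = model.embedding[:, 0]
        ours = (y @ M @ y) / (y @ y)
        dirs = rng.normal(size=(10_000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        Y = X @ dirs.T
        quotients = np.einsum("ni,nm,mi->i", Y, M, Y) / np.einsum("ni,ni->i", Y, Y)
        assert ours <= quotients.min() + 1e-10

    def test_eigen_residuals_small(self, rng):
        X = rng.normal(size=(20, 5))
        X = X - X.mean(axis=0)
        g = _knn_graph(X, k=4)
        w = compute_reconstruction_weights(X, g)
        model = fit_npe(X, w, d=3)
        IW = sp.identity(20) - w.W
        M = (IW.T @ IW).toarray()
        left = X.T @ M @ X
        right = X.T @ X
        right_reg = right + GRAM_EPS * np.mean(np.diag(right)) * np.eye(5)
        for j in range(3):
            p = model.projection[:, j]
            lam = model.eigenvalues[j]
            res = np.linalg.norm(left @ p - lam * right_reg @ p) / np.linalg.norm(p)
            assert res < 1e-8

    def test_eigenvalues_sorted_and_columns_vary(self, rng):
        X = rng.normal(size=(25, 6))
        g = _knn_graph(X, k=5)
        model = fit_npe(X, compute_reconstruction_weights(X, g), d=3)
        assert np.all(np.diff(model.eigenvalues) >= -1e-12)
        assert np.all(model.embedding.std(axis=0) > 0)

    def test_invariance_to_orthogonal_input_rotation(self, rng):
        X = rng.normal(size=(18, 4))
        X = X - X.mean(axis=0)
        Q = np.linalg.qr(rng.normal(size=(4, 4)))[0]
        g = _knn_graph(X, k=4)  # distances invariant under Q
        w = compute_reconstruction_weights(X, g)
        w_rot = compute_reconstruction_weights(X @ Q, g)
        Y1 = fit_npe(X, w, d=2).embedding
        Y2 = fit_npe(X @ Q, w_rot, d=2).embedding
        for j in range(2):
            sign = np.sign(Y1[:, j] @ Y2[:, j])
            np.testing.assert_allclose(Y1[:, j], sign * Y2[:, j], atol=1e-6)

    def test_linear_manifold_has_tiny_residual_cost(self, rng):
        """Data exactly on a 2-d linear manifold: the embedding preserves
        local reconstructions almost perfectly."""
        from npembed import fit_svd, transform_svd

        scores = rng.normal(size=(30, 2))
        load = np.linalg.qr(rng.normal(size=(5, 2)))[0].T
        raw = scores @ load
        X = transform_svd(raw, fit_svd(raw, 1.0))  # full-rank coordinates
        g = _knn_graph(X, k=4)
        # k > manifold dim + 1 makes the local Gram singular by construction;
        # a weak ridge keeps the affine reconstructions essentially exact
        w = compute_reconstruction_weights(X, g, ridge=1e-8)
        model = fit_npe(X, w, d=2)
        Y = model.embedding
        resid = Y - w.W @ Y
        assert np.sum(resid ** 2) < 1e-6 * np.sum(Y ** 2)

    def test_d_exceeding_q_is_error(self, rng):
        X = rng.normal(size=(10, 2))
        g = _knn_graph(X, k=3)
        with pytest.raises(DataError, match="exceeds"):
            fit_npe(X, compute_reconstruction_weights(X, g), d=5)


class TestTransform:
    def _fitted(self, rng, n=20, D=12):
        from npembed import fit_svd, transform_svd
        X = rng.normal(size=(n, D))
        red = fit_svd(X, 0.99)
        Xr = transform_svd(X, red)
        g = _knn_graph(Xr, k=4)
        w = compute_reconstruction_weights(Xr, g)
        return X, fit_npe(Xr, w, d=2, reduction=red)

    def test_training_rows_reproduce_stored_embedding(self, rng):
        X, model = self._fitted(rng)
        np.testing.assert_allclose(transform_npe(X, model), model.embedding,
                                   atol=1e-10)

    def test_training_mean_maps_to_zero(self, rng):
        X, model = self._fitted(rng)
        np.testing.assert_allclose(
            transform_npe(model.reduction.mean[None, :], model), 0.0, atol=1e-10)

    def test_mixtures_map_to_the_segment(self, rng):
        """Linearity: convex mixtures of two training rows embed on the
        segment between the two embeddings."""
        X, model = self._fitted(rng)
        y0, y1 = transform_npe(X[[0, 1]], model)
        for lam in (0.25, 0.5, 0.75):
            mix = lam * X[0] + (1 - lam) * X[1]
            y = transform_npe(mix[None, :], model)[0]
            np.testing.assert_allclose(y, lam * y0 + (1 - lam) * y1, atol=1e-8)

    def test_embedding_vectors_shape_and_zscore(self, rng):
        X, model = self._fitted(rng)
        V = model.embedding_vectors()
        assert V.shape == (X.shape[1], 2)
        Vz = model.embedding_vectors(z_score=True)
        np.testing.assert_allclose(Vz.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Vz.std(axis=0), 1.0, atol=1e-10)
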