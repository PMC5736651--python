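"""Neighbourhood-preserving embedding: reconstruction weights and the
linear projection.

Each subject is approximated as an affine combination of its graph
neighbours (weights summing to one, found from the local Gram system), and
a linear projection P is then sought that preserves those local
relations in d dimensions: P solves the generalized symmetric eigenproblem

    X' M X p = lambda X' X p,      M = (I - W)' (I - W),

over the SVD-reduced data X, taking the eigenvectors of the d smallest
eigenvalues.  Because the map is linear, unseen subjects are projected onto
the manifold without recomputing the embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .adjacency import NeighbourGraph
from .io import DataError
from .preprocessing import SvdReduction, transform_svd

#: Relative ridge added to an ill-conditioned local Gram matrix.
DEFAULT_RIDGE = 1e-3
#: Condition-number threshold above which the ridge is applied.
GRAM_COND_MAX = 1e12
#: Relative jitter that keeps the right-hand side X'X positive definite.
GRAM_EPS = 1e-9


@dataclass
class ReconstructionWeights:
    """Sparse row-stochastic weights supported on the neighbour graph."""

    W: sp.csr_matrix
    regularized: np.ndarray  # bool per row: ridge applied to the Gram system

    @property
    def n(self) -> int:
        return self.W.shape[0]


def compute_reconstruction_weights(Xr: np.ndarray, graph: NeighbourGraph,
                                   ridge: float = DEFAULT_RIDGE) -> ReconstructionWeights:
    """Per-subject affine reconstruction weights over the neighbour graph.

    Row i minimizes ``||x_i - sum_j w_j x_j||^2`` subject to ``sum w = 1``
    via the local Gram system G w = 1 (then normalized).  If G is singular
    or has condition above 1e12, ``ridge * trace(G) / k`` is added to its
    diagonal and the row is flagged.
    """
    Xr = np.asarray(Xr, dtype=float)
    n = Xr.shape[0]
    if graph.n != n:
        raise DataError("graph size does not match data")
    rows, cols, vals = [], [], []
    flagged = np.zeros(n, dtype=bool)
    for i in range(n):
        nb = np.asarray(graph.neighbours[i], dtype=int)
        if nb.size == 0:
            raise DataError(f"subject index {i} has an empty neighbour list")
        Z = Xr[nb] - Xr[i]
        G = Z @ Z.T
        k_i = nb.size
        tr = float(np.trace(G))
        cond = np.linalg.cond(G) if tr > 0 else np.inf
        if not np.isfinite(cond) or cond > GRAM_COND_MAX:
            G = G + np.eye(k_i) * (ridge * tr / k_i if tr > 0 else ridge)
            flagged[i] = True
        try:
            w = np.linalg.solve(G, np.ones(k_i))
        except np.linalg.LinAlgError:
            G = G + np.eye(k_i) * (ridge * tr / k_i if tr > 0 else ridge)
            flagged[i] = True
            w = np.linalg.solve(G, np.ones(k_i))
        w = w / w.sum()
        rows.extend([i] * k_i)
        cols.extend(nb.tolist())
        vals.extend(w.tolist())
    W = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return ReconstructionWeights(W, flagged)


@dataclass
class NPEModel:
    """Fitted embedding: SVD reduction composed with projection P."""

    reduction: SvdReduction
    projection: np.ndarray    # q x d, unit-norm sign-fixed columns
    embedding: np.ndarray     # n x d training coordinates, Y = Xr P
    eigenvalues: np.ndarray   # d smallest, ascending

    @property
    def d(self) -> int:
        return self.projection.shape[1]

    def embedding_vectors(self, z_score: bool = False) -> np.ndarray:
        """High-dimensional coefficient maps, one length-D vector per axis.

        These are the feature-space weights (basis @ P) that project a raw
        map onto each manifold coordinate — interpretable as spatial
        patterns of feature importance; optionally z-scored for display.
        """
        V = self.reduction.basis @ self.projection
        if z_score:
            V = (V - V.mean(axis=0)) / V.std(axis=0)
        return V


def _fix_columns(P: np.ndarray) -> np.ndarray:
    """Unit-norm columns with the largest-magnitude entry positive."""
    P = P / np.linalg.norm(P, axis=0)
    for j in range(P.shape[1]):
        imax = int(np.argmax(np.abs(P[:, j])))
        if P[imax, j] < 0:
            P[:, j] = -P[:, j]
    return P


def fit_npe(Xr: np.ndarray, weights: ReconstructionWeights, d: int,
            reduction: SvdReduction = None) -> NPEModel:
    """Solve the NPE generalized eigenproblem for the projection P.

    The right-hand side Gram matrix is regularized by
    ``GRAM_EPS * mean(diag) * I`` to guarantee definiteness; the
    eigenvectors of the d smallest eigenvalues form P, columns normalized
    to unit length with deterministic sign.
    """
    Xr = np.asarray(Xr, dtype=float)
    n, q = Xr.shape
    if d > q:
        raise DataError(f"d={d} exceeds reduced dimension q={q}")
    if n <= d:
        raise DataError(f"need more subjects ({n}) than dimensions ({d})")
    W = weights.W
    IW = sp.identity(n, format="csr") - W
    M = (IW.T @ IW).toarray()
    left = Xr.T @ M @ Xr
    right = Xr.T @ Xr
    right = right + GRAM_EPS * float(np.mean(np.diag(right))) * np.eye(q)
    left = (left + left.T) / 2.0
    right = (right + right.T) / 2.0
    eigvals, eigvecs = scipy.linalg.eigh(left, right,
                                         subset_by_index=(0, d - 1))
    if eigvecs.shape[1] < d:
        raise DataError(f"only {eigvecs.shape[1]} non-degenerate eigenvectors "
                        f"available, d={d} requested")
    P = _fix_columns(eigvecs)
    Y = Xr @ P
    return NPEModel(reduction, P, Y, np.maximum(eigvals, 0.0))


def transform_npe(X_new_raw: np.ndarray, model: NPEModel) -> np.ndarray:
    """Project raw feature rows onto the manifold (SVD reduce, then P)."""
    if model.reduction is None:
        raise DataError("model has no composed SVD reduction; pass reduced "
                        "rows through `model.projection` directly")
    Xr = transform_svd(X_new_raw, model.reduction)
    return Xr @ model.projection
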