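"""Supervised neighbour-graph construction.

Neighbourhoods are selected from the combination of a normalised image
similarity A (Gaussian kernel on Euclidean distance in the SVD-reduced
space) and an age similarity a (Gaussian kernel on age difference), under
two supervision masks: a sex-match constraint (A_ij = 0 when sexes differ)
and an optional site-mismatch constraint (A_ij = 0 when sites are equal, so
neighbourhoods cross scanners).  Bandwidths default to the median
heuristic, which pins the pair at the median (squared) distance to a
similarity of exp(-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .io import DataError, SubjectTable


@dataclass
class SimilarityMatrix:
    """Symmetric n x n similarity in [0, 1] with the bandwidth used."""

    values: np.ndarray
    bandwidth: float
    kind: str  # "image" or "age"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DataError("similarity matrix must be square")
        if np.abs(v - v.T).max() > 1e-12:
            raise DataError("similarity matrix must be symmetric")
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise DataError("similarity entries must lie in [0, 1]")


@dataclass
class NeighbourGraph:
    """Per-subject ordered neighbour lists with combined scores.

    ``neighbours[i]`` holds up to k indices sorted by descending combined
    score (ties to the smaller index); ``short_rows`` flags subjects whose
    eligibility fell below k under the active masks.
    """

    neighbours: list
    scores: list
    k: int
    combination_mode: str
    masks: dict = field(default_factory=dict)
    short_rows: np.ndarray = None

    @property
    def n(self) -> int:
        return len(self.neighbours)

    def indicator(self) -> np.ndarray:
        """Dense n x n boolean adjacency (i -> its neighbours)."""
        out = np.zeros((self.n, self.n), dtype=bool)
        for i, nb in enumerate(self.neighbours):
            out[i, nb] = True
        return out

    def to_edge_frame(self, subject_ids=None):
        """Edge list (subject, neighbour, rank, combined_score) for export."""
        import pandas as pd
        ids = (list(subject_ids) if subject_ids is not None
               else list(range(self.n)))
        rows = [(ids[i], ids[j], r + 1, float(s))
                for i, nb in enumerate(self.neighbours)
                for r, (j, s) in enumerate(zip(nb, self.scores[i]))]
        return pd.DataFrame(rows, columns=["subject_id", "neighbour_id",
                                           "rank", "combined_score"])


def _auto_sq_bandwidth(sq_dists: np.ndarray, what: str) -> float:
    nz = sq_dists[sq_dists > 0]
    if nz.size == 0:
        raise DataError(f"all {what} identical: auto bandwidth undefined")
    return float(np.median(nz))


def image_similarity(Xr: np.ndarray, bandwidth="auto") -> SimilarityMatrix:
    """A_ij = exp(-||x_i - x_j||^2 / sigma^2).

    Auto bandwidth: sigma^2 = median of nonzero squared pairwise distances.
    """
    Xr = np.asarray(Xr, dtype=float)
    if Xr.shape[0] < 2:
        raise DataError("image similarity needs at least 2 subjects")
    d2 = squareform(pdist(Xr, metric="sqeuclidean"))
    sigma_sq = _auto_sq_bandwidth(d2, "images") if bandwidth == "auto" \
        else float(bandwidth) ** 2
    A = np.exp(-d2 / sigma_sq)
    A = (A + A.T) / 2.0
    return SimilarityMatrix(A, float(np.sqrt(sigma_sq)), "image")


def age_similarity(table, bandwidth="auto") -> SimilarityMatrix:
    """a_ij = exp(-(age_i - age_j)^2 / tau^2).

    Auto bandwidth: tau = median nonzero absolute pairwise age difference.
    Accepts a SubjectTable or a plain age vector.
    """
    age = table.age if isinstance(table, SubjectTable) else np.asarray(table, float)
    if age.shape[0] < 2:
        raise DataError("age similarity needs at least 2 subjects")
    diff = np.abs(age[:, None] - age[None, :])
    if bandwidth == "auto":
        nz = diff[diff > 0]
        if nz.size == 0:
            raise DataError("all ages identical: auto bandwidth undefined")
        tau = float(np.median(nz))
    else:
        tau = float(bandwidth)
    a = np.exp(-(diff / tau) ** 2)
    a = (a + a.T) / 2.0
    return SimilarityMatrix(a, tau, "age")


def apply_constraints(A: SimilarityMatrix, table: SubjectTable,
                      use_site: bool = False) -> np.ndarray:
    """Zero similarities between different-sex pairs (and, with ``use_site``,
    same-site pairs) and on the diagonal.  A fully-zero row is legal here;
    it is dealt with at selection."""
    M = A.values.copy()
    sex = table.sex_code
    M[sex[:, None] != sex[None, :]] = 0.0
    if use_site:
        site = table.site
        M[site[:, None] == site[None, :]] = 0.0
    np.fill_diagonal(M, 0.0)
    return M


def combine_and_select(A_masked: np.ndarray, a: SimilarityMatrix, k: int,
                       mode: str = "product", weight: float = 0.5) -> NeighbourGraph:
    """Combine image and age similarity and pick each subject's top-k.

    ``product``: C = A_masked * a elementwise.  ``weighted_sum``:
    C = weight*A_masked + (1-weight)*a with A_masked's zero pattern
    re-applied (so masked pairs stay ineligible).  Per row, the k largest
    strictly positive entries are selected, ties broken toward the smaller
    index; rows with fewer than k eligible entries are flagged short, and a
    row with none is an error naming the subject.
    """
    if k < 1:
        raise DataError("k must be >= 1")
    av = a.values if isinstance(a, SimilarityMatrix) else np.asarray(a, float)
    if mode == "product":
        C = A_masked * av
    elif mode == "weighted_sum":
        C = weight * A_masked + (1.0 - weight) * av
        C[A_masked == 0.0] = 0.0
    else:
        raise DataError(f"unknown combination mode {mode!r}")
    np.fill_diagonal(C, 0.0)

    n = C.shape[0]
    neighbours, scores = [], []
    short = np.zeros(n, dtype=bool)
    for i in range(n):
        eligible = np.flatnonzero(C[i] > 0.0)
        if eligible.size == 0:
            masks = "sex-match" + (", site-mismatch" if np.all(A_masked[i] == 0) else "")
            raise DataError(
                f"subject index {i} has no eligible neighbours under the active "
                f"masks ({masks}); consider disabling the site constraint")
        # descending score, ascending index on ties
        order = np.lexsort((eligible, -C[i, eligible]))
        sel = eligible[order[:k]]
        if sel.size < k:
            short[i] = True
        neighbours.append(sel)
        scores.append(C[i, sel])
    return NeighbourGraph(neighbours, scores, k, mode,
                          masks={"sex": True, "site": bool(np.any(A_masked == 0))},
                          short_rows=short)


def build_graph(Xr: np.ndarray, table: SubjectTable, config) -> NeighbourGraph:
    """Full supervised graph for one metric under a RunConfig."""
    A = image_similarity(Xr, config.image_bandwidth)
    a = age_similarity(table, config.age_bandwidth)
    A_masked = apply_constraints(A, table, use_site=config.use_site_constraint)
    try:
        return combine_and_select(A_masked, a, config.k,
                                  config.combination_mode, config.weight_lambda)
    except DataError:
        if not config.use_site_constraint:
            raise
        # site constraint can starve small sites; retry without it, as it has
        # little effect on the embedding itself
        A_masked = apply_constraints(A, table, use_site=False)
        return combine_and_select(A_masked, a, config.k,
                                  config.combination_mode, config.weight_lambda)
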