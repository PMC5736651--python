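"""Axis rotation and the joint multi-metric manifold.

Each per-metric manifold is rotated by an orthogonal matrix R so that its
first axis correlates maximally with age and its second (orthogonally) with
sex; the rotated coordinate blocks are then concatenated
``Y_c = (Y_v, Y_t, Y_a)`` and summarised with PCA for the joint view.
Predictors consume the concatenated coordinates themselves; the joint PCA
exists for visualisation and reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DataError


@dataclass
class AxisRotation:
    """Orthogonal d x d rotation with the achieved target correlations."""

    R: np.ndarray
    axis1_age_correlation: float
    axis2_sex_correlation: float

    def apply(self, Y: np.ndarray) -> np.ndarray:
        return np.asarray(Y, dtype=float) @ self.R


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.linalg.norm(x) * np.linalg.norm(y)
    return float(x @ y / denom) if denom > 0 else 0.0


def _max_corr_direction(Yc: np.ndarray, target: np.ndarray,
                        basis: np.ndarray = None) -> np.ndarray:
    """Unit direction maximizing |corr(Y r, target)|, optionally restricted
    to the column span of ``basis``.

    The maximizer is the least-squares coefficient direction of the centred
    target on the centred coordinates (fitted values of an OLS have maximal
    correlation with the response among linear combinations).
    """
    t = target - target.mean()
    B = basis if basis is not None else np.eye(Yc.shape[1])
    Z = Yc @ B
    coef, *_ = np.linalg.lstsq(Z, t, rcond=None)
    r = B @ coef
    norm = np.linalg.norm(r)
    if norm == 0:
        raise DataError("target has no correlation direction in this space")
    return r / norm


def fit_axis_rotation(Y: np.ndarray, age: np.ndarray,
                      sex_code: np.ndarray) -> AxisRotation:
    """Orthogonal rotation aligning axis 1 with age and axis 2 with sex.

    Column 1 of R maximizes |corr(Y r, age)|; column 2 maximizes
    |corr(Y r, sex)| subject to orthogonality with column 1 (exact
    constrained maximizer via OLS in the orthogonal complement); remaining
    columns complete the basis by Gram-Schmidt over canonical axes,
    smallest index first.  Signs are fixed so both target correlations are
    positive.
    """
    Y = np.asarray(Y, dtype=float)
    age = np.asarray(age, dtype=float)
    sex_code = np.asarray(sex_code, dtype=float)
    d = Y.shape[1]
    if d < 2:
        raise DataError("axis rotation needs d >= 2")
    if np.ptp(age) == 0 or np.ptp(sex_code) == 0:
        raise DataError("age and sex must be non-constant for rotation")
    Yc = Y - Y.mean(axis=0)

    r1 = _max_corr_direction(Yc, age)
    if _corr(Y @ r1, age) < 0:
        r1 = -r1

    # orthonormal basis of the complement of r1
    full = np.linalg.qr(np.column_stack([r1, np.eye(d)]))[0]
    comp = full[:, 1:d]
    r2 = _max_corr_direction(Yc, sex_code, basis=comp)
    if _corr(Y @ r2, sex_code) < 0:
        r2 = -r2

    # complete deterministically: Gram-Schmidt of canonical axes
    cols = [r1, r2]
    for j in range(d):
        if len(cols) == d:
            break
        v = np.zeros(d)
        v[j] = 1.0
        for c in cols:
            v = v - (v @ c) * c
        norm = np.linalg.norm(v)
        if norm > 1e-10:
            cols.append(v / norm)
    R = np.column_stack(cols)
    return AxisRotation(R, _corr(Y @ r1, age), _corr(Y @ r2, sex_code))


@dataclass
class JointCoordinates:
    """Concatenated rotated per-metric coordinates plus their joint PCA."""

    Y_c: np.ndarray              # n x sum(d_m)
    block_labels: list           # metric name per column
    pca_loadings: np.ndarray     # p x p (columns = components)
    pca_means: np.ndarray
    pca_scores: np.ndarray       # n x p
    explained_variance_ratio: np.ndarray


def concatenate_and_pca(blocks: dict) -> JointCoordinates:
    """Assemble Y_c from per-metric blocks (canonical order volume,
    thickness, area over the blocks present) and run PCA on it.

    Components are sorted by variance with deterministic sign (the
    largest-magnitude loading is positive).
    """
    order = [m for m in ("volume", "thickness", "area") if m in blocks]
    if not order:
        raise DataError("no coordinate blocks given")
    n = next(iter(blocks.values())).shape[0]
    mats, labels = [], []
    for m in order:
        B = np.asarray(blocks[m], dtype=float)
        if B.shape[0] != n:
            raise DataError(f"block {m!r} has {B.shape[0]} rows, expected {n}")
        mats.append(B)
        labels.extend([m] * B.shape[1])
    Y_c = np.hstack(mats)
    mean = Y_c.mean(axis=0)
    Xc = Y_c - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    V = Vt.T
    for j in range(V.shape[1]):
        imax = int(np.argmax(np.abs(V[:, j])))
        if V[imax, j] < 0:
            V[:, j] = -V[:, j]
    scores = Xc @ V
    var = s ** 2
    ratio = var / var.sum() if var.sum() > 0 else var
    return JointCoordinates(Y_c, labels, V, mean, scores, ratio)
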