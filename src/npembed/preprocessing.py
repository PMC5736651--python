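"""Mean-centring, SVD variance reduction and global-scale correction.

All statistics here are fitted on training subjects and applied to any
subject set, so the cross-validation harness can keep held-out data out of
every fit.  Global-scale correction residualizes each feature against the
metric's global covariate (intracranial volume for tissue volume, total
surface area for area, mean cortical thickness for thickness) with a
per-feature ordinary least-squares fit; a ratio variant (divide by
covariate over its training mean) is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import DataError, MetricMatrix, SubjectTable


@dataclass
class ScaleCorrection:
    """Per-feature linear fit of feature value on a global covariate."""

    metric: str
    covariate_name: str
    method: str                  # "residual" or "ratio"
    intercept: np.ndarray        # length D
    slope: np.ndarray            # length D
    covariate_mean: float
    n_fit: int                   # training subjects used
    feature_ids: list

    def __post_init__(self) -> None:
        self.intercept = np.asarray(self.intercept, dtype=float)
        self.slope = np.asarray(self.slope, dtype=float)
        if self.intercept.shape != self.slope.shape:
            raise DataError("intercept/slope length mismatch")


def fit_scale_correction(matrix: MetricMatrix, table: SubjectTable,
                         method: str = "residual",
                         covariate: Optional[str] = None) -> ScaleCorrection:
    """Fit the global-scale correction on the given (training) subjects.

    The covariate defaults to the metric's canonical one but is configurable
    (e.g. parenchymal volume instead of ICV).
    """
    cov_name = covariate or matrix.global_covariate_name
    g = table.column(cov_name)
    if list(table.subject_ids) != list(matrix.subjects):
        raise DataError("table and matrix subject order differ; join first")
    if not np.all(g > 0):
        raise DataError(f"covariate {cov_name!r} must be strictly positive")
    if np.ptp(g) == 0:
        raise DataError(f"covariate {cov_name!r} is constant; correction undefined")
    gc = g - g.mean()
    X = matrix.values
    if method == "residual":
        slope = gc @ (X - X.mean(axis=0)) / (gc @ gc)
        intercept = X.mean(axis=0) - slope * g.mean()
    elif method == "ratio":
        slope = np.zeros(X.shape[1])
        intercept = np.zeros(X.shape[1])
    else:
        raise DataError(f"unknown scale correction method {method!r}")
    return ScaleCorrection(matrix.metric, cov_name, method, intercept, slope,
                           float(g.mean()), len(table), list(matrix.features))


def apply_scale_correction(matrix: MetricMatrix, correction: ScaleCorrection,
                           table: SubjectTable) -> MetricMatrix:
    """Replace values by scale-corrected values; shape and ids preserved."""
    if correction.feature_ids is not None and \
            list(matrix.features) != list(correction.feature_ids):
        raise DataError("feature ids do not match the fitted correction")
    g = table.column(correction.covariate_name)
    if correction.method == "ratio":
        out = matrix.values / (g / correction.covariate_mean)[:, None]
    else:
        out = matrix.values - (correction.intercept + np.outer(g, correction.slope))
    return MetricMatrix(matrix.metric, matrix.subjects, matrix.features, out)


@dataclass
class SvdReduction:
    """Mean vector plus orthonormal basis retaining a variance fraction."""

    mean: np.ndarray              # length D
    basis: np.ndarray             # D x q, orthonormal columns
    singular_values: np.ndarray   # length q
    variance_fraction_achieved: float

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.basis = np.asarray(self.basis, dtype=float)
        self.singular_values = np.asarray(self.singular_values, dtype=float)

    @property
    def q(self) -> int:
        return self.basis.shape[1]


def fit_svd(matrix, variance_retained: float = 0.95) -> SvdReduction:
    """Mean-centre and keep the smallest orthonormal basis reaching the
    requested cumulative squared-singular-value fraction (capped at rank).

    Accepts a MetricMatrix or a plain 2-d array.
    """
    X = matrix.values if isinstance(matrix, MetricMatrix) else np.asarray(matrix, float)
    n = X.shape[0]
    if n < 2:
        raise DataError("SVD reduction needs at least 2 subjects")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s ** 2))
    if total == 0.0:
        raise DataError("matrix is constant across subjects; zero variance")
    # numerical rank cut
    rank = int(np.sum(s > s[0] * max(X.shape) * np.finfo(float).eps))
    s = s[:rank]
    Vt = Vt[:rank]
    frac = np.cumsum(s ** 2) / total
    q = int(np.searchsorted(frac, variance_retained - 1e-12) + 1)
    q = min(q, rank)
    return SvdReduction(mean, Vt[:q].T.copy(), s[:q].copy(), float(frac[q - 1]))


def transform_svd(X, reduction: SvdReduction) -> np.ndarray:
    """Project raw rows into the reduced space: ``(x - mean) @ basis``."""
    X = X.values if isinstance(X, MetricMatrix) else np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != reduction.mean.shape[0]:
        raise DataError(f"feature count {X.shape[1]} != fitted "
                        f"{reduction.mean.shape[0]}")
    return (X - reduction.mean) @ reduction.basis
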