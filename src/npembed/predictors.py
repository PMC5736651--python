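"""Age regression and sex classification on manifold coordinates.

Age is predicted with Gaussian-process regression (squared-exponential
kernel with an isotropic length-scale plus additive white noise,
hyperparameters by marginal-likelihood maximization with seeded restarts);
sex with a linear discriminant classifier (empirical priors, automatic
shrinkage of the pooled covariance only when it is ill-conditioned).
Features are standardized with training-fold statistics; zero-variance
features are dropped with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .io import DataError

logger = logging.getLogger("npembed")

MIN_TRAIN_AGE = 20        # refuse hyperparameter fitting below this n
NOISE_FLOOR = 1e-6        # lower bound on the GP noise variance
LDA_COND_MAX = 1e8        # pooled-covariance condition triggering shrinkage


@dataclass
class _Standardizer:
    mean: np.ndarray = None
    std: np.ndarray = None
    keep: np.ndarray = None

    def fit(self, X: np.ndarray) -> "_Standardizer":
        X = np.asarray(X, dtype=float)
        std = X.std(axis=0)
        # relative tolerance: a constant column differs from 0 only by
        # floating-point cancellation in the mean subtraction
        tiny = 1e-12 * np.maximum(1.0, np.abs(X).max(axis=0, initial=0.0))
        self.keep = std > tiny
        if not self.keep.all():
            logger.warning("dropping %d zero-variance feature(s)",
                           int((~self.keep).sum()))
        if not self.keep.any():
            raise DataError("all features have zero variance")
        self.mean = X.mean(axis=0)[self.keep]
        self.std = std[self.keep]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise DataError("non-finite coordinates passed to a predictor")
        return (X[:, self.keep] - self.mean) / self.std


@dataclass
class AgeRegressor:
    """GP regression of age on coordinates; deterministic given seed."""

    seed: int = 0
    n_restarts: int = 3
    scaler: _Standardizer = None
    gp: GaussianProcessRegressor = None
    constant_age: float = None
    theta_: np.ndarray = None

    def _kernel(self):
        return (ConstantKernel(1.0, (1e-3, 1e3))
                * RBF(length_scale=1.0, length_scale_bounds=(1e-2, 1e3))
                + WhiteKernel(noise_level=1e-2,
                              noise_level_bounds=(NOISE_FLOOR, 1e2)))

    def fit(self, coords: np.ndarray, age: np.ndarray) -> "AgeRegressor":
        coords = np.asarray(coords, dtype=float)
        age = np.asarray(age, dtype=float)
        if coords.shape[0] < MIN_TRAIN_AGE:
            raise DataError(f"need >= {MIN_TRAIN_AGE} training subjects for "
                            f"GP hyperparameter fitting, got {coords.shape[0]}")
        if np.ptp(age) == 0:
            self.constant_age = float(age[0])
            return self
        self.scaler = _Standardizer().fit(coords)
        X = self.scaler.transform(coords)
        self.gp = GaussianProcessRegressor(
            kernel=self._kernel(), normalize_y=True,
            n_restarts_optimizer=self.n_restarts, random_state=self.seed)
        self.gp.fit(X, age)
        self.theta_ = self.gp.kernel_.theta.copy()
        return self

    def refit_fixed(self, coords: np.ndarray, age: np.ndarray,
                    theta: np.ndarray) -> "AgeRegressor":
        """Rebuild from stored hyperparameters without re-optimizing."""
        self.scaler = _Standardizer().fit(coords)
        X = self.scaler.transform(coords)
        kernel = self._kernel().clone_with_theta(np.asarray(theta, float))
        self.gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                           optimizer=None)
        self.gp.fit(X, np.asarray(age, float))
        self.theta_ = self.gp.kernel_.theta.copy()
        return self

    def predict(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        if self.constant_age is not None:
            return np.full(coords.shape[0], self.constant_age)
        pred = self.gp.predict(self.scaler.transform(coords))
        if not np.all(np.isfinite(pred)):
            raise DataError("GP produced a non-finite prediction")
        return pred


@dataclass
class SexClassifier:
    """Linear discriminant on coordinates, classes coded -1/+1."""

    scaler: _Standardizer = None
    lda: LinearDiscriminantAnalysis = None
    shrinkage_used: bool = False

    def fit(self, coords: np.ndarray, sex_code: np.ndarray) -> "SexClassifier":
        coords = np.asarray(coords, dtype=float)
        sex_code = np.asarray(sex_code, dtype=float)
        classes = np.unique(sex_code)
        if classes.size < 2:
            raise DataError("sex classifier needs both classes in training")
        self.scaler = _Standardizer().fit(coords)
        X = self.scaler.transform(coords)
        pooled = sum(np.cov(X[sex_code == c], rowvar=False)
                     * (np.sum(sex_code == c) - 1) for c in classes)
        pooled = pooled / (X.shape[0] - classes.size)
        cond = np.linalg.cond(np.atleast_2d(pooled))
        if not np.isfinite(cond) or cond > LDA_COND_MAX:
            self.shrinkage_used = True
            self.lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        else:
            self.lda = LinearDiscriminantAnalysis(solver="svd")
        self.lda.fit(X, sex_code)
        return self

    def predict(self, coords: np.ndarray):
        """Return ``(labels in -1/+1, probability of the +1 class)``."""
        X = self.scaler.transform(np.asarray(coords, dtype=float))
        labels = self.lda.predict(X)
        proba = self.lda.predict_proba(X)
        plus_col = int(np.argmax(self.lda.classes_))
        return labels, proba[:, plus_col]


def fit_predict_age(train_coords, train_age, test_coords,
                    seed: int = 0, n_restarts: int = 3) -> np.ndarray:
    """One-shot GP age prediction (fit on train, predict on test)."""
    return AgeRegressor(seed=seed, n_restarts=n_restarts) \
        .fit(train_coords, train_age).predict(test_coords)


def fit_predict_sex(train_coords, train_sex_code, test_coords):
    """One-shot LDA sex prediction; returns (labels, p_plus)."""
    return SexClassifier().fit(train_coords, train_sex_code).predict(test_coords)
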