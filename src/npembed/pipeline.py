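"""End-to-end supervised-NPE model: fit, out-of-sample transform, predict,
serialize.

`SupervisedNPEModel.fit` runs, per metric: optional global-scale
correction, SVD variance reduction, supervised neighbour graph,
reconstruction weights, the NPE eigenproblem, and the age/sex axis
rotation; the rotated per-metric coordinates are concatenated into the
joint representation that feeds the GP age regressor and LDA sex
classifier.  Every statistic is fitted only on the subjects passed to
``fit``, so the cross-validation harness can hold subjects out safely.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .adjacency import build_graph
from .config import RunConfig
from .io import DataError, MetricMatrix, SubjectTable
from .joint import AxisRotation, JointCoordinates, concatenate_and_pca, fit_axis_rotation
from .npe import NPEModel, compute_reconstruction_weights, fit_npe, transform_npe
from .predictors import AgeRegressor, SexClassifier
from .preprocessing import (ScaleCorrection, apply_scale_correction,
                            fit_scale_correction, fit_svd, transform_svd)


@dataclass
class MetricModel:
    """Everything fitted for one metric block."""

    metric: str
    scale: Optional[ScaleCorrection]
    npe: NPEModel
    rotation: AxisRotation

    def transform(self, matrix: MetricMatrix,
                  table: Optional[SubjectTable]) -> np.ndarray:
        if self.scale is not None:
            if table is None:
                raise DataError("scale-corrected model needs a subject table "
                                "to transform new data")
            matrix = apply_scale_correction(matrix, self.scale, table)
        return self.rotation.apply(transform_npe(matrix.values, self.npe))


class SupervisedNPEModel:
    """Fitted multi-metric manifold model with age and sex predictors."""

    def __init__(self, config: RunConfig, sex_coding, metric_models,
                 joint: JointCoordinates, age_model: AgeRegressor,
                 sex_model: SexClassifier, train_subjects):
        self.config = config
        self.sex_coding = tuple(sex_coding)
        self.metric_models = metric_models
        self.joint = joint
        self.age_model = age_model
        self.sex_model = sex_model
        self.train_subjects = list(train_subjects)

    # -- fitting -----------------------------------------------------------

    @classmethod
    def fit(cls, table: SubjectTable, matrices: dict,
            config: RunConfig) -> "SupervisedNPEModel":
        missing = [m for m in config.metrics if m not in matrices]
        if missing:
            raise DataError(f"missing metric matrices: {missing}")
        metric_models, blocks = {}, {}
        for metric in config.metrics:
            matrix = matrices[metric]
            if list(matrix.subjects) != list(table.subject_ids):
                raise DataError(f"{metric} matrix order differs from table; "
                                "join the cohort first")
            scale = None
            if config.global_scale_correction:
                scale = fit_scale_correction(matrix, table,
                                             method=config.scale_correction_method)
                matrix = apply_scale_correction(matrix, scale, table)
            reduction = fit_svd(matrix, config.variance_retained)
            Xr = transform_svd(matrix, reduction)
            graph = build_graph(Xr, table, config)
            weights = compute_reconstruction_weights(Xr, graph)
            npe = fit_npe(Xr, weights, config.d, reduction=reduction)
            if config.d >= 2:
                rotation = fit_axis_rotation(npe.embedding, table.age,
                                             table.sex_code)
            else:
                rotation = AxisRotation(np.eye(config.d), np.nan, np.nan)
            metric_models[metric] = MetricModel(metric, scale, npe, rotation)
            blocks[metric] = rotation.apply(npe.embedding)
        joint = concatenate_and_pca(blocks)
        age_model = AgeRegressor(seed=config.random_seed,
                                 n_restarts=config.gp_restarts)
        age_model.fit(joint.Y_c, table.age)
        sex_model = SexClassifier().fit(joint.Y_c, table.sex_code)
        model = cls(config, table.sex_coding, metric_models, joint,
                    age_model, sex_model, table.subject_ids)
        model._train_age_arr = table.age
        model._train_sex_arr = table.sex_code
        return model

    # -- application -------------------------------------------------------

    def transform(self, matrices: dict,
                  table: Optional[SubjectTable] = None) -> np.ndarray:
        """Concatenated rotated manifold coordinates for new subjects."""
        blocks = []
        for metric in self.config.metrics:
            if metric not in matrices:
                raise DataError(f"matrix for metric {metric!r} missing")
            blocks.append(self.metric_models[metric].transform(
                matrices[metric], table))
        return np.hstack(blocks)

    def predict(self, matrices: dict,
                table: Optional[SubjectTable] = None) -> dict:
        """Predicted age (years), sex labels and +1-class probability."""
        coords = self.transform(matrices, table)
        pred_age = self.age_model.predict(coords)
        code, p_plus = self.sex_model.predict(coords)
        labels = np.where(code > 0, self.sex_coding[1], self.sex_coding[0])
        return {"coords": coords, "predicted_age": pred_age,
                "predicted_sex_code": code, "predicted_sex": labels,
                "p_plus": p_plus}

    # -- diagnostics -------------------------------------------------------

    def fingerprint(self) -> str:
        """SHA-256 over every fitted parameter array (leakage audits)."""
        h = hashlib.sha256()
        for metric in self.config.metrics:
            mm = self.metric_models[metric]
            if mm.scale is not None:
                h.update(mm.scale.intercept.tobytes())
                h.update(mm.scale.slope.tobytes())
            h.update(mm.npe.reduction.mean.tobytes())
            h.update(mm.npe.reduction.basis.tobytes())
            h.update(mm.npe.projection.tobytes())
            h.update(mm.rotation.R.tobytes())
        h.update(self.joint.pca_loadings.tobytes())
        if self.age_model.theta_ is not None:
            h.update(np.asarray(self.age_model.theta_).tobytes())
        h.update(np.asarray(self.sex_model.lda.coef_, dtype=float).tobytes())
        return h.hexdigest()

    # -- serialization -----------------------------------------------------

    def save(self, path) -> None:
        """Single .npz archive: config, sex coding, SVD bases, projections,
        rotations, GP hyperparameters and the training coordinates needed to
        reconstruct the predictors exactly."""
        header = {
            "config": self.config.to_dict(),
            "sex_coding": list(self.sex_coding),
            "train_subjects": self.train_subjects,
            "gp_theta": (None if self.age_model.theta_ is None
                         else list(map(float, self.age_model.theta_))),
            "constant_age": self.age_model.constant_age,
        }
        arrays = {"_header": np.frombuffer(
            json.dumps(header, sort_keys=True).encode(), dtype=np.uint8)}
        for metric, mm in self.metric_models.items():
            p = f"metric_{metric}_"
            if mm.scale is not None:
                arrays[p + "scale_intercept"] = mm.scale.intercept
                arrays[p + "scale_slope"] = mm.scale.slope
                arrays[p + "scale_mean"] = np.array([mm.scale.covariate_mean])
            arrays[p + "mean"] = mm.npe.reduction.mean
            arrays[p + "basis"] = mm.npe.reduction.basis
            arrays[p + "singular_values"] = mm.npe.reduction.singular_values
            arrays[p + "projection"] = mm.npe.projection
            arrays[p + "embedding"] = mm.npe.embedding
            arrays[p + "eigenvalues"] = mm.npe.eigenvalues
            arrays[p + "rotation"] = mm.rotation.R
        arrays["joint_Yc"] = self.joint.Y_c
        arrays["joint_loadings"] = self.joint.pca_loadings
        arrays["train_age"] = np.asarray(self._train_age_arr)
        arrays["train_sex_code"] = np.asarray(self._train_sex_arr)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "SupervisedNPEModel":
        from .preprocessing import SvdReduction

        with np.load(path, allow_pickle=False) as npz:
            header = json.loads(bytes(npz["_header"]).decode())
            config = RunConfig.from_dict(header["config"])
            metric_models = {}
            for metric in config.metrics:
                p = f"metric_{metric}_"
                scale = None
                if p + "scale_intercept" in npz:
                    from .config import METRIC_COVARIATE
                    scale = ScaleCorrection(
                        metric, METRIC_COVARIATE[metric],
                        config.scale_correction_method,
                        npz[p + "scale_intercept"], npz[p + "scale_slope"],
                        float(npz[p + "scale_mean"][0]), 0,
                        feature_ids=None)
                red = SvdReduction(npz[p + "mean"], npz[p + "basis"],
                                   npz[p + "singular_values"], 1.0)
                npe = NPEModel(red, npz[p + "projection"],
                               npz[p + "embedding"], npz[p + "eigenvalues"])
                rotation = AxisRotation(npz[p + "rotation"], np.nan, np.nan)
                metric_models[metric] = MetricModel(metric, scale, npe, rotation)
            joint = concatenate_and_pca(
                _split_blocks(npz["joint_Yc"], config, metric_models))
            train_age = npz["train_age"]
            train_sex = npz["train_sex_code"]
            age_model = AgeRegressor(seed=config.random_seed,
                                     n_restarts=config.gp_restarts)
            if header["constant_age"] is not None:
                age_model.constant_age = float(header["constant_age"])
            else:
                age_model.refit_fixed(joint.Y_c, train_age,
                                      np.array(header["gp_theta"]))
            sex_model = SexClassifier().fit(joint.Y_c, train_sex)
            model = cls(config, header["sex_coding"], metric_models, joint,
                        age_model, sex_model, header["train_subjects"])
            model._train_age_arr = train_age
            model._train_sex_arr = train_sex
            return model


def _split_blocks(Yc: np.ndarray, config: RunConfig, metric_models) -> dict:
    blocks, start = {}, 0
    for metric in config.metrics:
        d = metric_models[metric].npe.d
        blocks[metric] = Yc[:, start:start + d]
        start += d
    return blocks


def fit_model(table: SubjectTable, matrices: dict,
              config: RunConfig) -> SupervisedNPEModel:
    """Functional alias for :meth:`SupervisedNPEModel.fit`."""
    return SupervisedNPEModel.fit(table, matrices, config)
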