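"""Cross-validated evaluation and the reported statistics.

`crossval_evaluate` runs the whole pipeline — scale correction, SVD, the
supervised graph, reconstruction weights, NPE, rotation and both
predictors — from scratch inside every training fold, projects the held-out
subjects, and pools the out-of-fold predictions into a report containing
MAE, the Pearson correlation between chronological and predicted age, sex
classification accuracy, age-binned and per-site tables, a one-way site
ANOVA of absolute error, and per-subject predictions.  Folds are
stratified by sex crossed with age decile (plain shuffled folds by
config), and every subject lands in the test set exactly once.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.model_selection import KFold, StratifiedKFold

from .config import RunConfig
from .io import DataError, SubjectTable, join_cohort
from .pipeline import SupervisedNPEModel

logger = logging.getLogger("npembed")


def make_folds(table: SubjectTable, config: RunConfig) -> list:
    """Seeded fold assignment: list of (train_idx, test_idx) arrays.

    Stratification uses sex crossed with age quantile bins (deciles when
    cohort size allows, coarser otherwise).  If some training fold ends up
    single-sex the stratification is re-randomized once before failing.
    """
    n = len(table)
    if n < 2 * config.n_folds:
        raise DataError(f"cohort of {n} too small for {config.n_folds} folds")
    for attempt, seed in enumerate((config.random_seed, config.random_seed + 1)):
        if config.stratified_folds:
            strata = _strata(table, config.n_folds, n_bins=10)
            splitter = StratifiedKFold(config.n_folds, shuffle=True,
                                       random_state=seed)
            folds = list(splitter.split(np.zeros(n), strata))
        else:
            splitter = KFold(config.n_folds, shuffle=True, random_state=seed)
            folds = list(splitter.split(np.zeros(n)))
        sex = table.sex_code
        if all(np.unique(sex[tr]).size == 2 for tr, _ in folds):
            return folds
        logger.warning("fold with a single sex class; re-randomizing "
                       "stratification (attempt %d)", attempt + 1)
    raise DataError("could not build folds with both sexes in every "
                    "training fold")


def _strata(table: SubjectTable, n_folds: int, n_bins: int) -> np.ndarray:
    age = table.age
    sex = table.sex_code
    for bins in range(n_bins, 0, -1):
        if bins > 1:
            q = pd.qcut(age, bins, labels=False, duplicates="drop")
        else:
            q = np.zeros(len(age), dtype=int)
        label = q * 2 + (sex > 0).astype(int)
        _, counts = np.unique(label, return_counts=True)
        if counts.min() >= n_folds:
            return label
    return (sex > 0).astype(int)


@dataclass
class EvaluationReport:
    """Pooled out-of-fold evaluation of the full pipeline."""

    mae: float
    pearson_r: float
    accuracy: float
    n_subjects: int
    config: dict
    binned: list                      # rows of the age-binned table
    per_site: list                    # per-site MAE / accuracy rows
    site_anova: dict                  # F, df1, df2, p
    predictions: list                 # per-subject rows
    fold_fingerprints: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    def predictions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.predictions)


def crossval_evaluate(table: SubjectTable, matrices: dict,
                      config: RunConfig, folds=None) -> EvaluationReport:
    """Leakage-safe k-fold evaluation of the full supervised-NPE pipeline."""
    table, matrices, _ = join_cohort(table, matrices)
    if folds is None:
        folds = make_folds(table, config)
    ids = table.subject_ids
    n = len(table)
    pred_age = np.full(n, np.nan)
    pred_sex = np.full(n, np.nan)
    p_plus = np.full(n, np.nan)
    fold_of = np.full(n, -1)
    fingerprints = []
    for f, (train_idx, test_idx) in enumerate(folds):
        model = fit_fold(table, matrices, config, train_idx)
        fingerprints.append(model.fingerprint())
        test_ids = ids[test_idx]
        test_table = table.subset(test_ids)
        test_matrices = {m: matrices[m].reorder(list(test_ids))
                         for m in config.metrics}
        out = model.predict(test_matrices, test_table)
        pred_age[test_idx] = out["predicted_age"]
        pred_sex[test_idx] = out["predicted_sex_code"]
        p_plus[test_idx] = out["p_plus"]
        fold_of[test_idx] = f
    if np.any(fold_of < 0):
        raise DataError("some subjects never appeared in a test fold")

    age = table.age
    sex = table.sex_code
    err = pred_age - age
    mae = float(np.mean(np.abs(err)))
    pearson_r = float(np.corrcoef(age, pred_age)[0, 1])
    accuracy = float(np.mean(pred_sex == sex))

    pred_rows = [
        {"subject_id": str(ids[i]), "fold": int(fold_of[i]),
         "true_age": float(age[i]), "predicted_age": float(pred_age[i]),
         "error": float(err[i]), "true_sex": str(table.sex_labels[i]),
         "predicted_sex": str(table.sex_coding[1] if pred_sex[i] > 0
                              else table.sex_coding[0]),
         "p_plus": float(p_plus[i])}
        for i in range(n)]

    binned = binned_metrics(age, pred_age, sex, pred_sex,
                            n_bins=min(10, n // 2))
    per_site, anova = site_tables(np.abs(err), pred_sex == sex, table)
    return EvaluationReport(mae, pearson_r, accuracy, n, config.to_dict(),
                            binned, per_site, anova, pred_rows, fingerprints)


def fit_fold(table: SubjectTable, matrices: dict, config: RunConfig,
             train_idx) -> SupervisedNPEModel:
    """Fit the entire pipeline on the training rows only.

    The model never receives held-out rows, which is what makes the
    training-fold parameter fingerprints invariant to anything done to the
    test subjects."""
    train_idx = np.asarray(train_idx)
    train_table = table.iloc(train_idx)
    train_ids = list(train_table.subject_ids)
    train_matrices = {m: matrices[m].reorder(train_ids)
                      for m in config.metrics}
    return SupervisedNPEModel.fit(train_table, train_matrices, config)


def binned_metrics(true_age, pred_age, true_sex, pred_sex,
                   n_bins: int = 10) -> list:
    """Age-ordered, approximately equal-sized bins with per-bin MAE and
    classification accuracy (ties in age broken by smaller index)."""
    true_age = np.asarray(true_age, float)
    n = true_age.shape[0]
    if n < n_bins:
        raise DataError(f"cannot form {n_bins} bins from {n} subjects")
    order = np.argsort(true_age, kind="stable")
    rows = []
    for b, idx in enumerate(np.array_split(order, n_bins)):
        aerr = np.abs(np.asarray(pred_age, float)[idx] - true_age[idx])
        tsex = np.asarray(true_sex, float)[idx]
        rows.append({
            "bin": b + 1, "n": int(idx.size),
            "mean_age": float(true_age[idx].mean()),
            "mae": float(aerr.mean()),
            "n_male": int(np.sum(tsex > 0)),
            "accuracy": float(np.mean(np.asarray(pred_sex, float)[idx] == tsex)),
        })
    return rows


def site_tables(abs_err, sex_correct, table: SubjectTable):
    """Per-site MAE/accuracy rows plus the one-way ANOVA of absolute age
    error over sites (sites with < 2 subjects excluded with a warning)."""
    sites = table.site
    rows, groups = [], []
    for s in sorted(set(sites)):
        m = sites == s
        rows.append({"site": str(s), "n": int(m.sum()),
                     "mae": float(abs_err[m].mean()),
                     "accuracy": float(np.mean(sex_correct[m]))})
        if m.sum() >= 2:
            groups.append(abs_err[m])
        else:
            logger.warning("site %s has < 2 subjects; excluded from ANOVA", s)
    anova = site_anova_groups(groups)
    return rows, anova


def site_anova_groups(groups) -> dict:
    if len(groups) < 2:
        return {"F": float("nan"), "df1": 0, "df2": 0, "p": float("nan")}
    F, p = scipy.stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = int(sum(len(g) for g in groups)) - len(groups)
    return {"F": float(F), "df1": df1, "df2": df2, "p": float(p)}


def site_anova(abs_err, sites) -> dict:
    """One-way ANOVA of absolute age-prediction error grouped by site."""
    abs_err = np.asarray(abs_err, float)
    sites = np.asarray(sites)
    groups = [abs_err[sites == s] for s in sorted(set(sites))
              if np.sum(sites == s) >= 2]
    return site_anova_groups(groups)


def error_cognition_regression(error, table: SubjectTable, scores,
                               covariates=("age", "sex", "ses"),
                               alpha: float = 0.05) -> pd.DataFrame:
    """Two-stage association of brain-age error with cognition.

    Stage 1 residualizes each cognitive score on the covariates (OLS with
    intercept; ``sex`` means the -1/+1 coding); stage 2 regresses the
    residualized score on the predicted-age error, reporting per-score R²,
    F with df (1, n-2), p, and Bonferroni significance across scores.
    Subjects with a missing covariate or score are dropped (count reported
    in the ``n`` column).
    """
    error = np.asarray(error, float)
    design_cols = []
    for cov in covariates:
        if cov == "sex":
            design_cols.append(table.sex_code)
        elif cov == "age":
            design_cols.append(table.age)
        else:
            design_cols.append(table.data[cov].to_numpy(dtype=float))
    design = np.column_stack([np.ones(len(table))] + design_cols)

    rows = []
    for score_name in scores:
        y = table.data[score_name].to_numpy(dtype=float)
        ok = np.isfinite(y) & np.isfinite(error) & np.all(np.isfinite(design), axis=1)
        n = int(ok.sum())
        if n < 3:
            raise DataError(f"too few complete records for score {score_name!r}")
        X, yv, ev = design[ok], y[ok], error[ok]
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        resid = yv - X @ beta
        r = np.corrcoef(ev, resid)[0, 1]
        r2 = float(r ** 2)
        F = r2 * (n - 2) / (1.0 - r2) if r2 < 1.0 else float("inf")
        p = float(scipy.stats.f.sf(F, 1, n - 2))
        rows.append({"score": score_name, "n": n, "r2": r2, "F": float(F),
                     "df1": 1, "df2": n - 2, "p": p})
    df = pd.DataFrame(rows)
    df["significant_bonferroni"] = df["p"] < alpha / len(scores)
    return df
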