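"""Reading, validating and writing subject tables and metric matrices.

The canonical on-disk formats are inspectable delimited text (tab canonical,
comma accepted on read): a subject metadata table with at least
``subject_id``, ``age``, ``sex`` and ``site`` columns, and per-metric
matrices whose first column is ``subject_id`` and whose remaining columns
are feature values.  An ``.npz`` container is supported as an optional
binary optimization.  Parsing is strict: numbers use the ``.`` decimal
point, and a malformed numeric cell is a hard error rather than a silent
coercion; rows with *missing* required fields are dropped and reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import METRIC_COVARIATE, METRICS

logger = logging.getLogger("npembed")

REQUIRED_COLUMNS = ("subject_id", "age", "sex", "site")
OPTIONAL_NUMERIC = ("icv", "total_area", "mean_thickness")


class DataError(ValueError):
    """A validation failure in input data."""


@dataclass
class LoadReport:
    """Record of what a reader kept and dropped."""

    n_read: int = 0
    n_kept: int = 0
    dropped: list = field(default_factory=list)  # (subject_id or row, reason)
    warnings: list = field(default_factory=list)

    def add_drop(self, key, reason: str) -> None:
        self.dropped.append((key, reason))
        logger.warning("dropped %r: %s", key, reason)

    def warn(self, message: str) -> None:
        self.warnings.append(message)
        logger.warning(message)


@dataclass
class SubjectTable:
    """Validated per-subject attributes.

    ``data`` is indexed 0..n-1 with a ``subject_id`` column; ``sex_coding``
    is the declared (label_minus, label_plus) pair: the first label codes as
    -1 and the second as +1.
    """

    data: pd.DataFrame
    sex_coding: tuple

    def __post_init__(self) -> None:
        self.sex_coding = tuple(self.sex_coding)
        if len(self.sex_coding) != 2 or len(set(self.sex_coding)) != 2:
            raise DataError(f"sex_coding must be two distinct labels, got {self.sex_coding}")
        validate_subject_table(self)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.data["subject_id"].to_numpy()

    @property
    def age(self) -> np.ndarray:
        return self.data["age"].to_numpy(dtype=float)

    @property
    def sex_labels(self) -> np.ndarray:
        return self.data["sex"].to_numpy()

    @property
    def sex_code(self) -> np.ndarray:
        """Sex as -1/+1 in declaration order of ``sex_coding``."""
        return np.where(self.sex_labels == self.sex_coding[1], 1.0, -1.0)

    @property
    def site(self) -> np.ndarray:
        return self.data["site"].to_numpy()

    def has_column(self, name: str) -> bool:
        return name in self.data.columns and not self.data[name].isna().any()

    def column(self, name: str) -> np.ndarray:
        if not self.has_column(name):
            raise DataError(f"column {name!r} absent or incomplete in subject table")
        return self.data[name].to_numpy(dtype=float)

    def subset(self, subject_ids: Sequence[str]) -> "SubjectTable":
        """Rows for ``subject_ids``, in the given order."""
        idx = self.data.set_index("subject_id")
        missing = [s for s in subject_ids if s not in idx.index]
        if missing:
            raise DataError(f"subjects not in table: {missing[:5]}")
        sub = idx.loc[list(subject_ids)].reset_index()
        return SubjectTable(sub, self.sex_coding)

    def iloc(self, indices) -> "SubjectTable":
        return SubjectTable(self.data.iloc[np.asarray(indices)].reset_index(drop=True),
                            self.sex_coding)


def validate_subject_table(table: SubjectTable) -> None:
    df = table.data
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise DataError(f"subject table missing required column {col!r}")
    ids = df["subject_id"]
    dup = ids[ids.duplicated()]
    if len(dup):
        raise DataError(f"duplicate subject_id {dup.iloc[0]!r}")
    age = df["age"].to_numpy(dtype=float)
    if not np.all(np.isfinite(age)) or not np.all(age > 0):
        bad = df["subject_id"].iloc[int(np.argmin(np.isfinite(age) & (age > 0)))]
        raise DataError(f"age must be finite and > 0 (subject {bad!r})")
    levels = sorted(set(df["sex"].astype(str)))
    if len(levels) > 2:
        raise DataError(f"sex has {len(levels)} observed levels {levels}; exactly 2 allowed")
    extra = set(levels) - set(map(str, table.sex_coding))
    if extra:
        raise DataError(f"sex labels {sorted(extra)} not in declared coding {table.sex_coding}")
    if (df["site"].astype(str).str.len() == 0).any():
        raise DataError("empty site label")


def _strict_float(value, where: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise DataError(f"cannot parse {value!r} as a number at {where} "
                        "(decimal point '.', no locale commas)") from None


def _sniff_sep(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_subject_table(path, sex_coding=("F", "M")) -> tuple:
    """Read and validate a subject metadata table.

    Returns ``(SubjectTable, LoadReport)``.  Rows with missing required
    fields, non-positive or non-finite age are dropped and listed in the
    report; structural problems (missing column, duplicate id, >2 sex
    levels, malformed numbers) raise :class:`DataError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False,
                     na_values=[""])
    report = LoadReport(n_read=len(df))
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise DataError(f"subject table {path} missing required column {col!r}")

    keep = np.ones(len(df), dtype=bool)
    ages = np.full(len(df), np.nan)
    for i, row in df.iterrows():
        missing = [c for c in REQUIRED_COLUMNS if pd.isna(row[c])]
        if missing:
            keep[i] = False
            report.add_drop(row.get("subject_id", f"row {i}"), f"missing {missing}")
            continue
        a = _strict_float(row["age"], f"row {i}, column 'age'")
        if not np.isfinite(a) or a <= 0:
            keep[i] = False
            report.add_drop(row["subject_id"], f"age {a} not finite and positive")
            continue
        ages[i] = a

    df = df.loc[keep].reset_index(drop=True)
    out = pd.DataFrame({
        "subject_id": df["subject_id"].astype(str),
        "age": ages[keep],
        "sex": df["sex"].astype(str),
        "site": df["site"].astype(str),
    })
    # Optional columns: kept only when complete for every retained row.
    extra_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    for col in extra_cols:
        vals = df[col]
        if vals.isna().any():
            report.warn(f"optional column {col!r} incomplete "
                        f"({int(vals.isna().sum())} missing); flagged absent")
            continue
        try:
            out[col] = np.array([_strict_float(v, f"column {col!r}") for v in vals])
        except DataError:
            out[col] = vals.astype(str)  # non-numeric covariate, kept as labels
    table = SubjectTable(out, sex_coding)
    report.n_kept = len(table)
    return table, report


def write_subject_table(table: SubjectTable, path) -> None:
    """Canonical tab-delimited output (UTF-8, '.' decimal); exact round-trip."""
    table.data.to_csv(path, sep="\t", index=False)


@dataclass
class MetricMatrix:
    """One subjects-by-features morphometric block."""

    metric: str
    subjects: list
    features: list
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise DataError(f"unknown metric {self.metric!r}; valid: {METRICS}")
        self.subjects = list(self.subjects)
        self.features = list(self.features)
        self.values = np.asarray(self.values, dtype=float)
        n, d = self.values.shape
        if n != len(self.subjects) or d != len(self.features):
            raise DataError("values shape does not match subjects/features")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(
                f"non-finite value at row {i} (subject {self.subjects[i]!r}), "
                f"column {j} (feature {self.features[j]!r})")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def global_covariate_name(self) -> str:
        return METRIC_COVARIATE[self.metric]

    def reorder(self, subject_ids: Sequence[str]) -> "MetricMatrix":
        pos = {s: i for i, s in enumerate(self.subjects)}
        missing = [s for s in subject_ids if s not in pos]
        if missing:
            raise DataError(f"subjects not in matrix: {missing[:5]}")
        idx = [pos[s] for s in subject_ids]
        return MetricMatrix(self.metric, list(subject_ids), self.features,
                            self.values[idx])


def read_metric_matrix(path, metric: str, subjects: Optional[SubjectTable] = None,
                       feature_mask: Optional[np.ndarray] = None) -> tuple:
    """Read one metric matrix and align it with a subject table.

    Returns ``(MetricMatrix, LoadReport)``.  The matrix is reordered to the
    table's subject order restricted to the intersection; subjects present
    in only one input are reported.  ``feature_mask`` optionally restricts
    columns (boolean over features) and is recorded in the report.
    """
    path = Path(path)
    report = LoadReport()
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as npz:
            ids = [str(s) for s in npz["subjects"]]
            features = [str(f) for f in npz["features"]]
            values = np.asarray(npz["values"], dtype=float)
    else:
        df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False,
                         na_values=["", "nan", "NaN"])
        first = df.columns[0]
        ids = df[first].astype(str).tolist()
        features = list(df.columns[1:])
        raw = df.iloc[:, 1:]
        values = np.full(raw.shape, np.nan)
        for j, col in enumerate(raw.columns):
            colvals = raw[col]
            for i, v in enumerate(colvals):
                if pd.isna(v):
                    raise DataError(f"non-finite value at ({i}, {j}) in {path}")
                values[i, j] = _strict_float(v, f"({i}, {j}) in {path}")
    report.n_read = len(ids)

    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise DataError(f"non-finite value at ({i}, {j}) in {path}")

    if feature_mask is not None:
        feature_mask = np.asarray(feature_mask, dtype=bool)
        if feature_mask.shape != (len(features),):
            raise DataError("feature_mask length does not match feature count")
        features = [f for f, m in zip(features, feature_mask) if m]
        values = values[:, feature_mask]
        report.warn(f"feature mask applied: {int(feature_mask.sum())} of "
                    f"{len(feature_mask)} features kept")

    if subjects is not None:
        table_ids = list(subjects.subject_ids)
        in_matrix = set(ids)
        joined = [s for s in table_ids if s in in_matrix]
        for s in table_ids:
            if s not in in_matrix:
                report.add_drop(s, "in subject table but not in matrix")
        for s in ids:
            if s not in set(table_ids):
                report.add_drop(s, "in matrix but not in subject table")
        pos = {s: i for i, s in enumerate(ids)}
        values = values[[pos[s] for s in joined]]
        ids = joined
    m = MetricMatrix(metric, ids, features, values)
    report.n_kept = m.n_subjects
    return m, report


def write_metric_matrix(matrix: MetricMatrix, path) -> None:
    """Write a matrix in canonical tab-delimited form (or .npz if so named)."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, subjects=np.array(matrix.subjects, dtype=str),
                 features=np.array(matrix.features, dtype=str),
                 values=matrix.values)
        return
    df = pd.DataFrame(matrix.values, columns=matrix.features)
    df.insert(0, "subject_id", matrix.subjects)
    df.to_csv(path, sep="\t", index=False)


def join_cohort(table: SubjectTable, matrices: dict) -> tuple:
    """Restrict a table and metric matrices to their common subjects.

    Returns ``(SubjectTable, {metric: MetricMatrix}, LoadReport)`` with every
    matrix reordered to the table's (restricted) subject order.  Idempotent
    and order-stable: the surviving order is the table's.
    """
    report = LoadReport(n_read=len(table))
    common = list(table.subject_ids)
    for m in matrices.values():
        present = set(m.subjects)
        common = [s for s in common if s in present]
    for s in table.subject_ids:
        if s not in set(common):
            report.add_drop(s, "absent from at least one metric matrix")
    joined_table = table.subset(common)
    joined = {name: m.reorder(common) for name, m in matrices.items()}
    report.n_kept = len(common)
    return joined_table, joined, report


def flatten_nifti(paths, metric: str, subject_ids, mask=None) -> MetricMatrix:
    """Optional convenience: flatten NIfTI volumes into a MetricMatrix.

    ``mask`` is a boolean array with the image shape selecting the feature
    voxels; by default every voxel becomes a feature.  The core pipeline
    never depends on this reader (requires nibabel).
    """
    import nibabel as nib  # lazy optional import

    rows = []
    shape = None
    for p in paths:
        img = np.asarray(nib.load(str(p)).get_fdata(), dtype=float)
        if shape is None:
            shape = img.shape
            if mask is None:
                mask = np.ones(shape, dtype=bool)
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != shape:
                raise DataError("mask shape does not match image shape")
        elif img.shape != shape:
            raise DataError(f"image {p} shape {img.shape} != first image {shape}")
        rows.append(img[mask])
    features = [f"vox{i}" for i in np.flatnonzero(mask.ravel())]
    return MetricMatrix(metric, list(subject_ids), features, np.array(rows))
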