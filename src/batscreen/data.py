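"""Tabular data handling for Q-CHAT-10 style screening records.

The canonical layout has 21 attributes: ten binary questionnaire items
``A1``..``A10``, demographic fields (age, gender, ethnicity, jaundice at
birth, family history of pervasive developmental disorder, respondent type,
country, prior use of a screening app, an age-group code 0-3), the screening
score (the sum of the ten items) and a binary class label (1 = screened
positive for ASD).

This module provides CSV I/O, label encoding of categorical columns,
min-max (or z-score) feature scaling fitted on a training partition only,
and stratified train/test and k-fold splitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ITEM_COLUMNS = [f"A{i}" for i in range(1, 11)]

#: column name -> kind for the canonical 21-attribute layout
DEFAULT_SCHEMA: dict[str, str] = {
    **{c: "binary" for c in ITEM_COLUMNS},
    "age": "continuous",
    "gender": "categorical",
    "ethnicity": "categorical",
    "jaundice": "binary",
    "family_pdd": "binary",
    "respondent": "categorical",
    "country": "categorical",
    "used_app_before": "binary",
    "age_group": "categorical",
    "score": "continuous",
    "class": "binary",
}

CLASS_COLUMN = "class"
SCORE_COLUMN = "score"

_BOOL_MAP = {"yes": 1, "no": 0, "1": 1, "0": 0, "true": 1, "false": 0}


class SchemaError(ValueError):
    """Raised when a file does not match the expected column layout."""


class UnseenCategoryError(ValueError):
    """Raised when transforming a category absent from the fitted encoding."""


@dataclass
class Dataset:
    """An ordered collection of screening records plus a column schema."""

    frame: pd.DataFrame
    schema: dict[str, str]

    @property
    def n_records(self) -> int:
        return len(self.frame)

    @property
    def n_attributes(self) -> int:
        return len(self.schema)

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.schema if c != CLASS_COLUMN]

    @property
    def labels(self) -> np.ndarray:
        return self.frame[CLASS_COLUMN].to_numpy(dtype=int)

    def check_score_consistency(self) -> list[int]:
        """Return row positions whose score differs from the item sum."""
        if SCORE_COLUMN not in self.frame.columns:
            return []
        items = [c for c in ITEM_COLUMNS if c in self.frame.columns]
        if len(items) != 10:
            return []
        sums = self.frame[items].astype(int).sum(axis=1).to_numpy()
        scores = self.frame[SCORE_COLUMN].astype(int).to_numpy()
        return [int(i) for i in np.nonzero(sums != scores)[0]]

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.copy()
        for col, kind in self.schema.items():
            if kind == "binary" and col not in ITEM_COLUMNS and col != CLASS_COLUMN:
                out[col] = out[col].map({1: "yes", 0: "no"})
        out.to_csv(path, index=False)


def load_csv(
    path: str | Path,
    schema: dict[str, str] | None = None,
    missing: str = "impute",
) -> Dataset:
    """Load a screening dataset from CSV.

    Booleans accept ``yes``/``no``; ``?`` marks a missing value which is
    imputed (categorical mode / numeric median) or dropped row-wise when
    ``missing='drop'``.  A row whose score column disagrees with the sum of
    the ten items triggers a consistency warning listing the offending row
    positions; the data is loaded unchanged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema is None:
        schema = {c: DEFAULT_SCHEMA.get(c, "categorical") for c in raw.columns}
    missing_cols = [c for c in schema if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"columns missing from {path.name}: {missing_cols}")
    extra = [c for c in raw.columns if c not in schema]
    if extra:
        raise SchemaError(f"unexpected columns in {path.name}: {extra}")

    frame = raw.replace("?", np.nan)
    if missing == "drop":
        frame = frame.dropna().reset_index(drop=True)

    parsed = {}
    for col, kind in schema.items():
        s = frame[col]
        if kind == "binary":
            s = s.str.strip().str.lower().map(_BOOL_MAP).astype("float")
        elif kind == "continuous":
            s = pd.to_numeric(s, errors="coerce")
        parsed[col] = s
    frame = pd.DataFrame(parsed)

    if missing == "impute" and frame.isna().any().any():
        for col, kind in schema.items():
            if not frame[col].isna().any():
                continue
            if kind == "categorical":
                fill = frame[col].mode(dropna=True).iloc[0]
            else:
                fill = frame[col].median(skipna=True)
            frame[col] = frame[col].fillna(fill)
    frame = frame.dropna().reset_index(drop=True)
    for col, kind in schema.items():
        if kind == "binary":
            frame[col] = frame[col].astype(int)
        elif kind == "categorical":
            # numeric category codes (e.g. the age-group code) round-trip
            # as integers rather than strings
            numeric = pd.to_numeric(frame[col], errors="coerce")
            if not numeric.isna().any():
                if (numeric == numeric.round()).all():
                    numeric = numeric.astype(int)
                frame[col] = numeric

    ds = Dataset(frame=frame, schema=dict(schema))
    bad = ds.check_score_consistency()
    if bad:
        warnings.warn(
            f"screening score differs from item sum in rows {bad}",
            UserWarning,
            stacklevel=2,
        )
    return ds


# ---------------------------------------------------------------------------
# encoding and scaling


@dataclass
class EncodedMatrix:
    """Numeric feature matrix with the fitted encoding/scaling state."""

    features: np.ndarray
    labels: np.ndarray
    columns: list[str]
    encoding_maps: dict[str, dict] = field(default_factory=dict)
    scaling_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    scaling_mode: str | None = None

    def copy(self) -> "EncodedMatrix":
        return EncodedMatrix(
            features=self.features.copy(),
            labels=self.labels.copy(),
            columns=list(self.columns),
            encoding_maps={k: dict(v) for k, v in self.encoding_maps.items()},
            scaling_params=dict(self.scaling_params),
            scaling_mode=self.scaling_mode,
        )


def encode_column(values: pd.Series) -> tuple[np.ndarray, dict]:
    """Encode one categorical column as consecutive integers.

    Categories are mapped in lexicographic order starting at 0, so the
    encoding is deterministic across runs and platforms.
    """
    cats = sorted(values.astype(str).unique())
    mapping = {c: i for i, c in enumerate(cats)}
    return values.astype(str).map(mapping).to_numpy(dtype=float), mapping


def encode_labels(dataset: Dataset) -> EncodedMatrix:
    """Label-encode every categorical column of ``dataset``.

    Binary and continuous columns pass through as floats.  The per-column
    category->integer maps are retained so the encoding is invertible and
    can be applied to new data (an unseen category raises
    :class:`UnseenCategoryError`).
    """
    cols = dataset.feature_columns
    mats, maps = [], {}
    for col in cols:
        if dataset.schema[col] == "categorical":
            enc, mapping = encode_column(dataset.frame[col])
            maps[col] = mapping
            mats.append(enc)
        else:
            mats.append(dataset.frame[col].to_numpy(dtype=float))
    features = np.column_stack(mats) if cols else np.empty((dataset.n_records, 0))
    return EncodedMatrix(
        features=features,
        labels=dataset.labels,
        columns=cols,
        encoding_maps=maps,
    )


def apply_encoding(values: pd.Series, mapping: dict, column: str) -> np.ndarray:
    unseen = set(values.astype(str)) - set(mapping)
    if unseen:
        raise UnseenCategoryError(
            f"column {column!r}: categories {sorted(unseen)} not seen during fitting"
        )
    return values.astype(str).map(mapping).to_numpy(dtype=float)


def decode_column(codes: np.ndarray, mapping: dict) -> list:
    inverse = {v: k for k, v in mapping.items()}
    return [inverse[int(c)] for c in codes]


def minmax_scale(
    matrix: EncodedMatrix,
    fit_idx: np.ndarray | list[int],
    mode: str = "minmax",
) -> EncodedMatrix:
    """Scale features using statistics from ``fit_idx`` rows only.

    ``minmax`` maps each column to [0, 1] on the fitting partition (constant
    columns map to 0); ``zscore`` standardises to mean 0 / sd 1 instead.
    Rows outside ``fit_idx`` are transformed with the fitted statistics, so
    test values may fall outside [0, 1]; such columns are reported through a
    warning rather than clipped.
    """
    fit_idx = np.asarray(fit_idx, dtype=int)
    if fit_idx.size == 0:
        raise ValueError("fit_idx must be non-empty")
    X = matrix.features
    if not np.all(np.isfinite(X)):
        r, c = np.argwhere(~np.isfinite(X))[0]
        raise ValueError(f"non-finite value at row {r}, column {matrix.columns[c]!r}")
    out = matrix.copy()
    params: dict[str, tuple[float, float]] = {}
    scaled = np.empty_like(X, dtype=float)
    for j, col in enumerate(matrix.columns):
        sub = X[fit_idx, j]
        if mode == "minmax":
            lo, hi = float(sub.min()), float(sub.max())
            params[col] = (lo, hi)
            scaled[:, j] = 0.0 if hi == lo else (X[:, j] - lo) / (hi - lo)
        elif mode == "zscore":
            mu, sd = float(sub.mean()), float(sub.std())
            params[col] = (mu, sd)
            scaled[:, j] = 0.0 if sd == 0 else (X[:, j] - mu) / sd
        else:
            raise ValueError(f"unknown scaling mode {mode!r}")
    if mode == "minmax":
        mask = np.ones(len(X), dtype=bool)
        mask[fit_idx] = False
        if mask.any():
            oob = (scaled[mask] < 0) | (scaled[mask] > 1)
            if oob.any():
                cols = [matrix.columns[j] for j in np.nonzero(oob.any(axis=0))[0]]
                warnings.warn(
                    f"values outside the fitted [0, 1] range in columns {cols}",
                    UserWarning,
                    stacklevel=2,
                )
    out.features = scaled
    out.scaling_params = params
    out.scaling_mode = mode
    return out


def inverse_scale(matrix: EncodedMatrix) -> np.ndarray:
    """Undo the fitted scaling (constant columns cannot be recovered)."""
    if matrix.scaling_mode is None:
        return matrix.features.copy()
    X = matrix.features.copy()
    for j, col in enumerate(matrix.columns):
        a, b = matrix.scaling_params[col]
        if matrix.scaling_mode == "minmax":
            X[:, j] = X[:, j] * (b - a) + a if b != a else a
        else:
            X[:, j] = X[:, j] * b + a if b != 0 else a
    return X


# ---------------------------------------------------------------------------
# splitting


@dataclass
class SplitIndices:
    train_idx: np.ndarray
    test_idx: np.ndarray
    fold_assignments: np.ndarray | None = None


def split_train_test(
    n: int,
    test_fraction: float,
    labels: np.ndarray | list[int],
    seed: int,
) -> SplitIndices:
    """Stratified shuffle split, deterministic for a fixed seed."""
    labels = np.asarray(labels)
    if n < 2 or len(labels) != n:
        raise ValueError("need n >= 2 rows with one label each")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    test_parts, train_parts = [], []
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        rng.shuffle(idx)
        n_test = int(round(len(idx) * test_fraction))
        test_parts.append(idx[:n_test])
        train_parts.append(idx[n_test:])
    test_idx = np.sort(np.concatenate(test_parts))
    train_idx = np.sort(np.concatenate(train_parts))
    if len(test_idx) == 0 or len(train_idx) == 0:
        raise ValueError("test_fraction leaves an empty partition")
    return SplitIndices(train_idx=train_idx, test_idx=test_idx)


def kfold_indices(
    n: int,
    k: int,
    labels: np.ndarray | list[int],
    seed: int,
) -> SplitIndices:
    """Stratified k-fold assignment; every row lands in exactly one fold."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"cannot split {n} rows into {k} folds")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    offset = 0
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        rng.shuffle(idx)
        # round-robin with a rotating offset keeps fold sizes within 1 overall
        assign = (np.arange(len(idx)) + offset) % k
        folds[idx] = assign
        offset += len(idx)
    return SplitIndices(
        train_idx=np.arange(n),
        test_idx=np.array([], dtype=int),
        fold_assignments=folds,
    )


def fold_split(split: SplitIndices, fold: int) -> tuple[np.ndarray, np.ndarray]:
    """Train/test indices for one fold of a k-fold assignment."""
    if split.fold_assignments is None:
        raise ValueError("not a k-fold split")
    mask = split.fold_assignments == fold
    return np.nonzero(~mask)[0], np.nonzero(mask)[0]
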