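"""Labeled feature tables: delimited-text I/O, stratified splitting, standardization.

The optimizer's search substrate is a plain ``n_samples x d_features`` real
matrix with a binary label per row (0 = benign/negative, 1 = malignant/positive),
e.g. deep features extracted from mammogram patches.  Everything downstream
(wrapper fitness, SSD, ABHC) consumes :class:`LabeledTable` / :class:`SplitPair`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledTable",
    "SplitPair",
    "TableFormatError",
    "load_table",
    "write_table",
    "stratified_split",
    "standardize",
]


class TableFormatError(ValueError):
    """A delimited file violates the labeled-table contract."""


@dataclass
class LabeledTable:
    """A real feature matrix with one binary label per row.

    Parameters
    ----------
    features
        ``(n_samples, d_features)`` float array, unitless.
    labels
        Length ``n_samples`` integer vector over {0, 1}.
    feature_names
        ``d_features`` unique column names.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n, d = self.features.shape
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(d)]
        if len(self.feature_names) != d:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {d} features"
            )
        if len(set(self.feature_names)) != d:
            raise TableFormatError("duplicate feature names")
        if self.labels.shape != (n,):
            raise ValueError("labels length must equal number of rows")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary {0, 1}")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> tuple[int, int]:
        return int(np.sum(self.labels == 0)), int(np.sum(self.labels == 1))

    def subset_rows(self, idx: np.ndarray) -> "LabeledTable":
        return LabeledTable(self.features[idx], self.labels[idx], list(self.feature_names))


@dataclass
class SplitPair:
    """Row-disjoint train/test parts of one table (identical columns)."""

    train: LabeledTable
    test: LabeledTable

    def __post_init__(self) -> None:
        if self.train.feature_names != self.test.feature_names:
            raise ValueError("train/test column sets differ")


def load_table(path, label_column: str = "label", delimiter: str = ",") -> LabeledTable:
    """Read a delimited text file with a header row into a :class:`LabeledTable`.

    Any two distinct label values are accepted and mapped to {0, 1} by
    lexicographic order of their string form; the mapping is logged.
    Non-numeric feature cells raise :class:`TableFormatError` naming row and
    column.
    """
    try:
        frame = pd.read_csv(path, delimiter=delimiter)
    except FileNotFoundError:
        raise FileNotFoundError(f"no such table file: {path}") from None
    if label_column not in frame.columns:
        raise TableFormatError(
            f"label column {label_column!r} not found among {list(frame.columns)}"
        )
    feature_cols = [c for c in frame.columns if c != label_column]
    if not feature_cols:
        raise TableFormatError("table has no feature columns")
    if len(set(feature_cols)) != len(feature_cols):
        raise TableFormatError("duplicate feature names in header")

    feats = frame[feature_cols].apply(pd.to_numeric, errors="coerce")
    bad = feats.isna() & frame[feature_cols].notna()
    if bad.any().any() or feats.isna().any().any():
        nan_mask = feats.isna().to_numpy()
        row, col = np.argwhere(nan_mask)[0]
        raise TableFormatError(
            f"non-numeric feature cell at row {int(row)}, column {feature_cols[col]!r}"
        )

    raw = frame[label_column]
    uniques = sorted(map(str, pd.unique(raw.astype(str))))
    if len(uniques) > 2:
        raise TableFormatError(
            f"label column has {len(uniques)} distinct values; need at most 2"
        )
    mapping = {v: i for i, v in enumerate(uniques)}
    labels = raw.astype(str).map(mapping).to_numpy()
    if list(mapping) != ["0", "1"]:
        logger.info("label mapping (lexicographic): %s", mapping)
    return LabeledTable(feats.to_numpy(dtype=float), labels, feature_cols)


def write_table(table: LabeledTable, path, label_column: str = "label",
                delimiter: str = ",") -> None:
    """Write a table as delimited text; round-trips numbers to full precision."""
    frame = pd.DataFrame(table.features, columns=table.feature_names)
    frame[label_column] = table.labels
    frame.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def stratified_split(table: LabeledTable, test_fraction: float, seed: int) -> SplitPair:
    """Seeded stratified hold-out split preserving per-class proportions ±1 row.

    Each class must be able to contribute at least one row to each side.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    test_idx: list[np.ndarray] = []
    train_idx: list[np.ndarray] = []
    for cls in (0, 1):
        rows = np.flatnonzero(table.labels == cls)
        if rows.size < 2:
            raise ValueError(
                f"class {cls} has {rows.size} sample(s); need >=2 to split"
            )
        n_test = int(round(test_fraction * rows.size))
        n_test = min(max(n_test, 1), rows.size - 1)
        perm = rng.permutation(rows)
        test_idx.append(perm[:n_test])
        train_idx.append(perm[n_test:])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))
    return SplitPair(table.subset_rows(tr), table.subset_rows(te))


def standardize(train: LabeledTable, test: LabeledTable) -> SplitPair:
    """Z-score both parts with the training set's population (÷n) statistics.

    Constant training columns map to exactly 0 on both sides, which keeps the
    Euclidean metric well defined without dividing by zero.
    """
    if train.n_samples < 2:
        raise ValueError("need >=2 training rows to standardize")
    mu = train.features.mean(axis=0)
    sd = train.features.std(axis=0)  # population SD (ddof=0)
    safe = np.where(sd == 0.0, 1.0, sd)
    tr = (train.features - mu) / safe
    te = (test.features - mu) / safe
    const = sd == 0.0
    tr[:, const] = 0.0
    te[:, const] = 0.0
    return SplitPair(
        LabeledTable(tr, train.labels, list(train.feature_names)),
        LabeledTable(te, test.labels, list(test.feature_names)),
    )
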