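"""Labeled tabular datasets and preprocessing.

A :class:`LabeledDataset` holds a real-valued feature matrix ``X`` of shape
(n samples, d features), integer-coded class labels ``y`` and one identifier
per feature column.  All downstream weight learning assumes the columns have
been z-scored (:func:`standardize`), matching the usual preprocessing for
microarray / gene-expression matrices where features live on wildly
different scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LabeledDataset", "standardize", "load_csv"]


@dataclass
class LabeledDataset:
    """Feature matrix, integer class labels and feature identifiers.

    Parameters
    ----------
    X : ndarray of shape (n_samples, n_features)
        Real-valued feature matrix.
    y : ndarray of shape (n_samples,)
        Integer-coded class labels.
    feature_ids : list of str, optional
        One identifier per feature column; defaults to ``f1..fd``.
    label_names : list, optional
        Original label values in integer-code order (code ``i`` maps to
        ``label_names[i]``); kept for round-tripping output files.
    constant_features : ndarray of int
        Indices of zero-variance columns found during standardization.
    """

    X: np.ndarray
    y: np.ndarray
    feature_ids: list[str] | None = None
    label_names: list | None = None
    constant_features: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int)
    )

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional (samples x features)")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError(
                f"y has shape {self.y.shape}, expected ({self.X.shape[0]},)"
            )
        if self.feature_ids is None:
            self.feature_ids = [f"f{i + 1}" for i in range(self.X.shape[1])]
        elif len(self.feature_ids) != self.X.shape[1]:
            raise ValueError("feature_ids length does not match feature count")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return int(np.unique(self.y).size)

    def require_supervised(self) -> None:
        """Raise if the dataset cannot support supervised weight learning."""
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.n_classes < 2:
            raise ValueError("need at least 2 distinct class labels")

    def subset_features(self, indices: np.ndarray) -> "LabeledDataset":
        """View of the dataset restricted to the given feature columns."""
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(
            X=self.X[:, idx],
            y=self.y,
            feature_ids=[self.feature_ids[i] for i in idx],
            label_names=self.label_names,
        )


def standardize(ds: LabeledDataset) -> LabeledDataset:
    """Z-score every feature column: mean 0, standard deviation 1.

    Zero-variance columns cannot be scaled; they are set to all-zero and
    recorded in ``constant_features``.  Idempotent up to floating-point
    round-off.
    """
    X = np.asarray(ds.X, dtype=float)
    if not np.isfinite(X).all():
        bad = np.argwhere(~np.isfinite(X))[0]
        raise ValueError(
            f"non-finite value at row {bad[0]}, column "
            f"{ds.feature_ids[bad[1]]!r}"
        )
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    constant = np.flatnonzero(sd == 0.0)
    safe_sd = np.where(sd == 0.0, 1.0, sd)
    Z = (X - mean) / safe_sd
    Z[:, constant] = 0.0
    return LabeledDataset(
        X=Z,
        y=ds.y,
        feature_ids=list(ds.feature_ids),
        label_names=ds.label_names,
        constant_features=constant,
    )


def load_csv(
    path,
    label_col: str = "label",
    sep: str | None = None,
) -> LabeledDataset:
    """Read a delimited text file into a :class:`LabeledDataset`.

    One row per sample, header row of feature identifiers, one designated
    label column.  Labels (strings or integers) are factor-coded in order of
    first appearance; the original values are kept in ``label_names``.
    Missing values are an error.

    Parameters
    ----------
    path : str or path-like
        CSV/TSV file to read.
    label_col : str
        Name of the label column (default ``"label"``).
    sep : str, optional
        Field delimiter; sniffed from the file when omitted.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    if label_col not in df.columns:
        raise ValueError(
            f"label column {label_col!r} not found; columns are "
            f"{list(df.columns)}"
        )
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = int(df.index[df[col].isna()][0])
        raise ValueError(f"missing value at row {row}, column {col!r}")
    labels = df[label_col]
    features = df.drop(columns=[label_col])
    non_numeric = [
        c for c in features.columns
        if not np.issubdtype(features[c].dtype, np.number)
    ]
    if non_numeric:
        raise ValueError(f"non-numeric feature column(s): {non_numeric}")
    codes, uniques = pd.factorize(labels)
    return LabeledDataset(
        X=features.to_numpy(dtype=float),
        y=codes.astype(int),
        feature_ids=[str(c) for c in features.columns],
        label_names=list(uniques),
    )
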