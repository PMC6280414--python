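"""Feature-table container for binary imbalanced classification.

Convention used throughout the package: label 1 marks the minority
(abnormal/positive) class and label 0 the majority (normal/negative) class,
so the imbalance ratio IR = N+/N- lies in (0, 1] whenever the minority class
really is the rarer one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class DegenerateFeatureError(ValueError):
    """A feature column carries no information (e.g. constant)."""


class InsufficientDataError(ValueError):
    """Too few samples for the requested operation."""


@dataclass
class Dataset:
    """A numeric feature matrix with binary labels.

    Attributes
    ----------
    X : ndarray, shape (N, M)
        Real-valued feature matrix, one row per sample.
    y : ndarray, shape (N,)
        Binary labels; 1 = minority/positive, 0 = majority/negative.
    feature_names : list of str
        Column names; generated as ``f1..fM`` when absent.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {self.X.shape}")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError(
                f"y has shape {self.y.shape}, expected ({self.X.shape[0]},)"
            )
        labels = np.unique(self.y)
        if not np.all(np.isin(labels, [0, 1])):
            raise ValueError(f"labels must be binary 0/1, found {labels}")
        self.y = self.y.astype(int)
        if np.isnan(self.X).any():
            raise ValueError(
                "feature matrix contains missing values; impute or drop "
                "them before constructing a Dataset"
            )
        if not self.feature_names:
            self.feature_names = [f"f{i + 1}" for i in range(self.X.shape[1])]
        elif len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length does not match X columns")

    # -- derived counts -------------------------------------------------
    @property
    def n(self) -> int:
        """Total sample count N = N+ + N-."""
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_minority(self) -> int:
        """N+: samples with label 1."""
        return int(np.sum(self.y == 1))

    @property
    def n_majority(self) -> int:
        """N-: samples with label 0."""
        return int(np.sum(self.y == 0))

    @property
    def imbalance_ratio(self) -> float:
        """IR = N+/N-; in (0, 1] when the minority class is rarer."""
        if self.n_majority == 0:
            raise ZeroDivisionError("no majority samples; IR undefined")
        return self.n_minority / self.n_majority

    def minority_X(self) -> np.ndarray:
        return self.X[self.y == 1]

    def majority_X(self) -> np.ndarray:
        return self.X[self.y == 0]

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df[label_column] = self.y
        return df


def read_table(path, label_column: str = "label", sep: str | None = None) -> Dataset:
    """Read a CSV/TSV feature table into a :class:`Dataset`.

    The file must have a header row and one binary label column
    (``label_column``); all other columns are treated as real features.
    The delimiter is sniffed from the extension unless ``sep`` is given.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    if label_column not in df.columns:
        raise KeyError(
            f"label column {label_column!r} not found; columns: {list(df.columns)}"
        )
    y = df[label_column].to_numpy()
    feats = df.drop(columns=[label_column])
    return Dataset(feats.to_numpy(dtype=float), y, list(feats.columns))


def write_table(ds: Dataset, path, label_column: str = "label", sep: str = ",") -> None:
    """Write a :class:`Dataset` as a delimited table with a header row."""
    ds.to_frame(label_column).to_csv(path, sep=sep, index=False)
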