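"""Binary solution encoding, mask algebra, and feature-matrix subsetting.

A candidate feature subset is a length-``d`` vector of {0,1} (a
:class:`BinaryMask`); the data it is applied to is an ``n x d`` numeric
matrix with one integer class label per row (a :class:`FeatureMatrix`).
Feature indices are 0-based throughout the API; human-readable reports
additionally print the 1-based ``f1..fd`` names conventional in the EEG
feature-selection literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BinaryMask",
    "FeatureMatrix",
    "make_mask",
    "opposite",
    "subset_features",
    "reduction_rate",
]


@dataclass(frozen=True)
class BinaryMask:
    """An ordered, immutable vector of {0,1} selecting feature columns."""

    bits: tuple

    def __post_init__(self):
        bits = tuple(int(b) for b in self.bits)
        if any(b not in (0, 1) for b in bits):
            raise ValueError("mask bits must be 0 or 1")
        object.__setattr__(self, "bits", bits)

    @property
    def d(self) -> int:
        return len(self.bits)

    @property
    def n_selected(self) -> int:
        return int(sum(self.bits))

    @property
    def indices(self) -> tuple:
        """0-based indices of the selected features."""
        return tuple(j for j, b in enumerate(self.bits) if b)

    def to_array(self) -> np.ndarray:
        return np.asarray(self.bits, dtype=np.int8)

    def to_string(self) -> str:
        """Serialize as a '0'/'1' character string, e.g. ``'101010'``."""
        return "".join(str(b) for b in self.bits)

    @classmethod
    def from_string(cls, s: str) -> "BinaryMask":
        if not s or any(ch not in "01" for ch in s):
            raise ValueError(f"mask string must be nonempty over '0'/'1', got {s!r}")
        return cls(tuple(int(ch) for ch in s))

    def feature_names(self) -> tuple:
        """1-based ``f<j>`` labels of the selected features (reporting aid)."""
        return tuple(f"f{j + 1}" for j in self.indices)

    def __len__(self) -> int:
        return len(self.bits)

    def __iter__(self):
        return iter(self.bits)


@dataclass
class FeatureMatrix:
    """An ``n x d`` real feature matrix with per-sample integer labels.

    Construction rejects missing/non-finite values; fitness evaluation
    additionally requires at least two distinct labels.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list = field(default=None)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("feature values must be a 2-D matrix")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature matrix contains missing or non-finite values")
        labels = np.asarray(self.labels)
        if labels.ndim != 1 or labels.shape[0] != values.shape[0]:
            raise ValueError("labels must be one integer per sample row")
        labels = labels.astype(int)
        if self.feature_names is None:
            self.feature_names = [f"f{j + 1}" for j in range(values.shape[1])]
        elif len(self.feature_names) != values.shape[1]:
            raise ValueError("feature_names length must equal the feature count")
        else:
            self.feature_names = [str(c) for c in self.feature_names]
        self.values = values
        self.labels = labels

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return int(np.unique(self.labels).size)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str) -> "FeatureMatrix":
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not in dataframe")
        y = df[label_column].to_numpy()
        X = df.drop(columns=[label_column])
        return cls(X.to_numpy(dtype=float), y, list(X.columns))

    @classmethod
    def read_csv(cls, features_path, labels_path=None, label_column=None,
                 header: bool = True) -> "FeatureMatrix":
        """Read a comma-separated matrix, with labels either in a designated
        column or a separate one-value-per-line file."""
        df = pd.read_csv(features_path, header=0 if header else None)
        if label_column is not None:
            return cls.from_dataframe(df, str(label_column) if header else label_column)
        if labels_path is None:
            raise ValueError("provide labels_path or label_column")
        y = np.loadtxt(labels_path, dtype=float).astype(int).reshape(-1)
        names = list(df.columns.astype(str)) if header else None
        return cls(df.to_numpy(dtype=float), y, names)

    def to_csv(self, features_path, labels_path=None, label_column=None) -> None:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        if label_column is not None:
            df[label_column] = self.labels
            df.to_csv(features_path, index=False)
            return
        df.to_csv(features_path, index=False)
        if labels_path is not None:
            np.savetxt(labels_path, self.labels, fmt="%d")


def make_mask(indices: Iterable[int], d: int) -> BinaryMask:
    """Build the mask of length ``d`` selecting the given 0-based indices."""
    idx = set(int(i) for i in indices)
    if any(i < 0 or i >= d for i in idx):
        raise ValueError(f"feature index out of range [0, {d})")
    return BinaryMask(tuple(1 if j in idx else 0 for j in range(d)))


def opposite(mask: BinaryMask) -> BinaryMask:
    """Bitwise complement of a mask; an involution."""
    return BinaryMask(tuple(1 - b for b in mask.bits))


def subset_features(F: FeatureMatrix, mask: BinaryMask) -> FeatureMatrix:
    """Columns of ``F`` where the mask bit is 1, in original order.

    The all-zeros mask yields an ``n x 0`` matrix (labels kept): the search
    can visit the empty subset and downstream code handles it explicitly.
    """
    if mask.d != F.d:
        raise ValueError(f"mask length {mask.d} != feature count {F.d}")
    cols = list(mask.indices)
    return FeatureMatrix(F.values[:, cols], F.labels,
                         [F.feature_names[j] for j in cols])


def reduction_rate(mask: BinaryMask) -> float:
    """Fraction of features discarded: 1 - (selected)/d."""
    if mask.d == 0:
        raise ValueError("reduction rate undefined for a zero-length mask")
    return 1.0 - mask.n_selected / mask.d
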