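"""Wrapper fitness: leave-one-out 1-nearest-neighbor accuracy, minimized.

The objective assigned to a candidate mask X is ``f(X) = 1 - Acc(X)``,
where Acc is leave-one-out cross-validated accuracy of a lightweight
classifier (default: 1-NN with Euclidean distance) on the masked matrix.
The empty mask is assigned the worst value 1.0 by convention instead of
raising, so the search space stays closed under opposition and movement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Protocol, runtime_checkable

import numpy as np
from scipy.spatial.distance import cdist

from .encoding import BinaryMask, FeatureMatrix, subset_features

__all__ = [
    "FitnessValue",
    "ClassifierAdapter",
    "OneNearestNeighbor",
    "euclidean_distance",
    "loocv_accuracy",
    "fitness",
    "FitnessCache",
]


@dataclass(frozen=True)
class FitnessValue:
    """Minimization objective ``value = 1 - accuracy`` for a mask.

    ``value == 1.0`` with ``n_selected == 0`` encodes the empty-mask penalty.
    """

    value: float
    accuracy: float
    n_selected: int


@runtime_checkable
class ClassifierAdapter(Protocol):
    """Pluggable classifier contract for the wrapper fitness.

    Implementations must be deterministic given identical inputs; any
    internal randomness must be seeded by the caller before use.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ClassifierAdapter": ...

    def predict(self, X: np.ndarray) -> np.ndarray: ...


class OneNearestNeighbor:
    """1-NN with Euclidean distance; ties go to the lowest training row index.

    Implemented directly so the tie rule is explicit and order-stable
    (``argmin`` returns the first minimum).
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OneNearestNeighbor":
        self._X = np.asarray(X, dtype=float)
        self._y = np.asarray(y)
        if self._X.ndim != 2 or self._X.shape[0] != self._y.shape[0]:
            raise ValueError("training matrix/labels shape mismatch")
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        D = cdist(np.asarray(X, dtype=float), self._X)
        return self._y[np.argmin(D, axis=1)]


def euclidean_distance(a, b) -> float:
    """Euclidean distance between two equal-length numeric vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def loocv_accuracy(F: FeatureMatrix, mask: BinaryMask,
                   clf: Optional[ClassifierAdapter] = None) -> float:
    """Leave-one-out accuracy of ``clf`` on the masked matrix.

    Each sample is predicted by the classifier trained on the other n-1
    masked rows. Requires a nonempty mask and n >= 2; callers that can
    produce the empty mask must go through :func:`fitness`.
    """
    if mask.n_selected == 0:
        raise ValueError("loocv_accuracy requires >=1 selected feature; "
                         "use fitness() which handles the empty mask")
    if F.n < 2:
        raise ValueError("LOOCV requires at least 2 samples")
    if F.n_classes < 2:
        raise ValueError("LOOCV accuracy requires at least 2 distinct labels")
    sub = subset_features(F, mask)
    X, y = sub.values, sub.labels
    clf = clf if clf is not None else OneNearestNeighbor()

    if isinstance(clf, OneNearestNeighbor):
        # Vectorized path: full pairwise distances, self excluded on the
        # diagonal. argmin keeps the lowest-index tie rule.
        D = cdist(X, X)
        np.fill_diagonal(D, np.inf)
        pred = y[np.argmin(D, axis=1)]
        return float(np.mean(pred == y))

    n = F.n
    correct = 0
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        pred = clf.fit(X[train], y[train]).predict(X[i:i + 1])
        correct += int(pred[0] == y[i])
    return correct / n


class FitnessCache(dict):
    """Memo of mask bit-string -> FitnessValue, cleared per run."""

    hits: int = 0


def fitness(F: FeatureMatrix, mask: BinaryMask,
            clf: Optional[ClassifierAdapter] = None,
            cache: Optional[FitnessCache] = None) -> FitnessValue:
    """Objective ``1 - LOOCV accuracy`` for a mask; 1.0 for the empty mask.

    The empty-mask penalty is returned without invoking the classifier.
    Results are memoized by exact bit string when a cache is supplied;
    the repeated-LOOCV cost is the dominant expense of the search.
    """
    if mask.d != F.d:
        raise ValueError(f"mask length {mask.d} != feature count {F.d}")
    key = mask.to_string()
    if cache is not None and key in cache:
        cache.hits += 1
        return cache[key]
    if mask.n_selected == 0:
        fv = FitnessValue(value=1.0, accuracy=0.0, n_selected=0)
    else:
        acc = loocv_accuracy(F, mask, clf)
        fv = FitnessValue(value=1.0 - acc, accuracy=acc,
                          n_selected=mask.n_selected)
    if cache is not None:
        cache[key] = fv
    return fv
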