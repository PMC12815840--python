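"""Classification metrics and cross-validated assessment of a selected mask.

Accuracy, precision, recall and F1 are computed from the confusion
table (TP, FP, FN, TN) for a stated positive label; multiclass inputs
are macro-averaged one-vs-rest. Zero-denominator precision/recall are
reported as 0 with an explicit flag rather than NaN, so aggregation
stays stable. ``evaluate_mask`` runs seeded stratified k-fold (or
leave-one-out) over the masked matrix and pools held-out predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Union

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .encoding import BinaryMask, FeatureMatrix, reduction_rate, subset_features
from .fitness import ClassifierAdapter, OneNearestNeighbor

__all__ = ["MetricsReport", "classification_metrics", "evaluate_mask"]


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: Dict[str, int]          # TP/FP/FN/TN (binary) or per-class
    reduction_rate: Optional[float] = None
    per_class: Optional[Dict] = None   # multiclass one-vs-rest breakdown
    degenerate: bool = False           # a zero-denominator metric was zeroed
    n_samples: int = 0


def _binary_metrics(tp: int, fp: int, fn: int, tn: int):
    n = tp + fp + fn + tn
    accuracy = (tp + tn) / n if n else 0.0
    degenerate = False
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, degenerate = 0.0, True
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, degenerate = 0.0, True
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return accuracy, precision, recall, f1, degenerate


def classification_metrics(y_true, y_pred,
                           positive_label=1) -> MetricsReport:
    """Confusion-table metrics; macro one-vs-rest when >2 classes appear."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length vectors")
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    classes = np.unique(np.concatenate([y_true, y_pred]))

    if classes.size <= 2:
        pos = positive_label
        tp = int(np.sum((y_true == pos) & (y_pred == pos)))
        fp = int(np.sum((y_true != pos) & (y_pred == pos)))
        fn = int(np.sum((y_true == pos) & (y_pred != pos)))
        tn = int(np.sum((y_true != pos) & (y_pred != pos)))
        acc, prec, rec, f1, degen = _binary_metrics(tp, fp, fn, tn)
        return MetricsReport(acc, prec, rec, f1,
                             {"TP": tp, "FP": fp, "FN": fn, "TN": tn},
                             degenerate=degen, n_samples=int(y_true.size))

    per_class = {}
    degen_any = False
    for cls in classes:
        tp = int(np.sum((y_true == cls) & (y_pred == cls)))
        fp = int(np.sum((y_true != cls) & (y_pred == cls)))
        fn = int(np.sum((y_true == cls) & (y_pred != cls)))
        tn = int(np.sum((y_true != cls) & (y_pred != cls)))
        _, prec, rec, f1, degen = _binary_metrics(tp, fp, fn, tn)
        degen_any |= degen
        per_class[cls] = {"precision": prec, "recall": rec, "f1": f1,
                          "TP": tp, "FP": fp, "FN": fn, "TN": tn}
    accuracy = float(np.mean(y_true == y_pred))
    precision = float(np.mean([m["precision"] for m in per_class.values()]))
    recall = float(np.mean([m["recall"] for m in per_class.values()]))
    f1 = float(np.mean([m["f1"] for m in per_class.values()]))
    confusion = {str(cls): {k: per_class[cls][k] for k in
                            ("TP", "FP", "FN", "TN")} for cls in classes}
    return MetricsReport(accuracy, precision, recall, f1, confusion,
                         per_class=per_class, degenerate=degen_any,
                         n_samples=int(y_true.size))


def evaluate_mask(F: FeatureMatrix, mask: BinaryMask,
                  clf: Optional[ClassifierAdapter] = None,
                  folds: Union[int, str] = 5, seed: int = 0,
                  positive_label=1) -> MetricsReport:
    """Cross-validated metrics of a classifier on the masked matrix.

    ``folds`` is an integer k >= 2 for seeded stratified k-fold or
    ``"loo"`` / n for leave-one-out. Predictions are pooled over the
    held-out folds before computing metrics, and the mask's reduction
    rate is attached to the report. If stratification cannot give every
    fold each class, the fold count is reduced with a warning.
    """
    if mask.n_selected == 0:
        raise ValueError("cannot evaluate the empty mask: no features selected")
    sub = subset_features(F, mask)
    X, y = sub.values, sub.labels
    n = F.n
    clf = clf if clf is not None else OneNearestNeighbor()
    y_pred = np.empty(n, dtype=y.dtype)

    loo = folds == "loo" or folds == n
    if loo:
        idx = np.arange(n)
        for i in range(n):
            train = idx != i
            y_pred[i] = clf.fit(X[train], y[train]).predict(X[i:i + 1])[0]
    else:
        folds = int(folds)
        if folds < 2:
            raise ValueError("folds must be >= 2 or 'loo'")
        min_class = int(np.bincount(np.unique(y, return_inverse=True)[1]).min())
        if folds > min_class:
            import warnings
            warnings.warn(f"reducing folds from {folds} to {min_class} so "
                          "every fold sees every class", stacklevel=2)
            folds = max(min_class, 2)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        for train, test in skf.split(X, y):
            y_pred[test] = clf.fit(X[train], y[train]).predict(X[test])

    report = classification_metrics(y, y_pred, positive_label=positive_label)
    report.reduction_rate = reduction_rate(mask)
    return report
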