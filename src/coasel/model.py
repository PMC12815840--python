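"""Model/Results front-end for coati feature selection.

``CoatiSelectionModel`` is built from a feature matrix (or DataFrame);
``fit()`` runs the coati search and returns ``CoatiSelectionResults``
carrying the selected mask, its wrapper fitness, the convergence trace
and diagnostics, with a ``summary()`` table, a convergence plot, and a
cross-validated ``evaluate()`` of the selected subset.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
import pandas as pd

from .coa_core import COAConfig, COAResult, run_coa
from .encoding import BinaryMask, FeatureMatrix, reduction_rate
from .evaluation import MetricsReport, evaluate_mask
from .fitness import ClassifierAdapter

__all__ = ["CoatiSelectionModel", "CoatiSelectionResults"]


class CoatiSelectionModel:
    """Wrapper feature selection on an n x d matrix with class labels.

    Parameters
    ----------
    features : FeatureMatrix, array-like, or DataFrame of shape (n, d)
    labels : per-sample integer class labels (ignored when ``features``
        is already a FeatureMatrix)
    classifier : optional ClassifierAdapter used inside the wrapper
        fitness; default is 1-NN with Euclidean distance.
    """

    def __init__(self, features, labels=None,
                 classifier: Optional[ClassifierAdapter] = None,
                 feature_names=None):
        if isinstance(features, FeatureMatrix):
            self.data = features
        elif isinstance(features, pd.DataFrame):
            self.data = FeatureMatrix(features.to_numpy(dtype=float),
                                      labels, list(features.columns))
        else:
            self.data = FeatureMatrix(np.asarray(features, dtype=float),
                                      labels, feature_names)
        if self.data.n_classes < 2:
            raise ValueError("feature selection requires >= 2 classes")
        self.classifier = classifier

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str,
                       classifier=None) -> "CoatiSelectionModel":
        return cls(FeatureMatrix.from_dataframe(df, label_column),
                   classifier=classifier)

    def fit(self, n_coatis: int = 20, n_iterations: int = 50,
            init_p: float = 0.5, seed: int = 0,
            early_stop_eps: float = 1e-6, early_stop_window: int = 10,
            callback=None) -> "CoatiSelectionResults":
        """Run the coati search and return the fitted results."""
        cfg = COAConfig(N=n_coatis, T=n_iterations, p=init_p, seed=seed,
                        early_stop_eps=early_stop_eps,
                        early_stop_window=early_stop_window)
        raw = run_coa(self.data, cfg, self.classifier, callback=callback)
        return CoatiSelectionResults(self, cfg, raw)


class CoatiSelectionResults:
    """Fitted results of a coati feature-selection run."""

    def __init__(self, model: CoatiSelectionModel, config: COAConfig,
                 raw: COAResult):
        self.model = model
        self.config = config
        self.raw = raw

    # -- primary estimates -------------------------------------------------
    @property
    def mask(self) -> BinaryMask:
        return self.raw.best_mask

    @property
    def selected_indices(self) -> tuple:
        return self.mask.indices

    @property
    def selected_names(self) -> tuple:
        return tuple(self.model.data.feature_names[j]
                     for j in self.mask.indices)

    @property
    def fitness(self) -> float:
        return self.raw.best_fitness.value

    @property
    def accuracy(self) -> float:
        """LOOCV wrapper accuracy of the selected subset."""
        return self.raw.best_fitness.accuracy

    @property
    def reduction_rate(self) -> float:
        return reduction_rate(self.mask)

    @property
    def trace(self) -> list:
        return list(self.raw.trace)

    @property
    def n_evaluations(self) -> int:
        return self.raw.n_evaluations

    # -- downstream --------------------------------------------------------
    def evaluate(self, folds: Union[int, str] = "loo",
                 seed: Optional[int] = None) -> MetricsReport:
        """Cross-validated metrics of the selected subset on the data."""
        return evaluate_mask(self.model.data, self.mask,
                             self.model.classifier, folds=folds,
                             seed=self.config.seed if seed is None else seed)

    def transform(self, X=None) -> np.ndarray:
        """Project a matrix (default: the training matrix) onto the
        selected columns."""
        X = self.model.data.values if X is None else np.asarray(X, dtype=float)
        return X[:, list(self.mask.indices)]

    def plot_convergence(self, ax=None):
        """Best-fitness trace per iteration (non-increasing by elitism)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.step(range(len(self.raw.trace)), self.raw.trace, where="post")
        ax.set_xlabel("iteration")
        ax.set_ylabel("best fitness  1 - LOOCV accuracy")
        ax.set_title("Coati search convergence")
        return ax

    def to_dict(self) -> dict:
        """JSON-ready report (0-based indices plus 1-based f-names)."""
        return {
            "mask": self.mask.to_string(),
            "selected_indices": list(self.mask.indices),
            "selected_features": list(self.mask.feature_names()),
            "fitness": self.fitness,
            "accuracy": self.accuracy,
            "reduction_rate": self.reduction_rate,
            "trace": self.trace,
            "n_evaluations": self.n_evaluations,
            "n_iterations": self.raw.n_iterations,
            "stopped_early": self.raw.stopped_early,
            "config": {
                "N": self.config.N, "T": self.config.T, "p": self.config.p,
                "seed": self.config.seed,
                "early_stop_eps": self.config.early_stop_eps,
                "early_stop_window": self.config.early_stop_window,
            },
        }

    def summary(self) -> str:
        """Human-readable summary table of the fitted selection."""
        d = self.model.data.d
        lines = [
            "Coati Feature Selection Results",
            "=" * 46,
            f"{'Samples':<28}{self.model.data.n:>18}",
            f"{'Features (d)':<28}{d:>18}",
            f"{'Population (N)':<28}{self.config.N:>18}",
            f"{'Max iterations (T)':<28}{self.config.T:>18}",
            f"{'Iterations run':<28}{self.raw.n_iterations:>18}",
            f"{'Seed':<28}{self.config.seed:>18}",
            f"{'Distinct masks evaluated':<28}{self.n_evaluations:>18}",
            "-" * 46,
            f"{'Selected features':<28}{self.mask.n_selected:>18}",
            f"{'Reduction rate':<28}{self.reduction_rate:>18.4f}",
            f"{'LOOCV accuracy':<28}{self.accuracy:>18.4f}",
            f"{'Fitness (1 - accuracy)':<28}{self.fitness:>18.4f}",
            "-" * 46,
            "Selected: " + ", ".join(self.selected_names),
            "=" * 46,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<CoatiSelectionResults: {self.mask.n_selected}/"
                f"{self.model.data.d} features, "
                f"fitness={self.fitness:.4f}>")
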