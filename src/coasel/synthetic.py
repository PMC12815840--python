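"""Synthetic benchmark generators with known ground truth.

Two generators mirror the data regimes the selectors target:

* a two-class tabular matrix in which a known subset of columns carries
  class-separated Gaussian signal (class-conditional means +-effect/2,
  unit variance) and the rest are pure standard-normal noise — the
  "irrelevant and redundant features" regime of high-dimensional
  biomedical matrices;
* epoched multichannel oscillatory trials whose class difference is
  band-power modulation on a known channel subset, emulating
  motor-imagery band-power effects on top of 1/f-ish background noise.

Both are pure functions of their spec (seed included) and return the
planted ground truth for recovery tests. A small hand-checkable 5x6
fixture with labels [1,1,0,0,0] is bundled for worked examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Set, Tuple

import numpy as np
import scipy.signal

from .encoding import FeatureMatrix
from .signal_features import EpochSet

__all__ = [
    "TabularSpec",
    "SignalSpec",
    "worked_example_fixture",
    "generate_tabular",
    "generate_signals",
]

# 5 trials x 6 features; features f1, f3, f5 separate class 1 (rows 1-2)
# from class 0 (rows 3-5)
_WORKED_EXAMPLE = np.array([
    [0.85, 0.47, 0.90, 0.11, 0.63, 0.40],
    [0.78, 0.50, 0.88, 0.14, 0.60, 0.42],
    [0.25, 0.33, 0.27, 0.92, 0.55, 0.49],
    [0.24, 0.36, 0.23, 0.89, 0.53, 0.50],
    [0.30, 0.29, 0.32, 0.94, 0.57, 0.52],
])
_WORKED_EXAMPLE_LABELS = np.array([1, 1, 0, 0, 0])


def worked_example_fixture() -> FeatureMatrix:
    """The bundled 5x6 two-class demonstration matrix."""
    return FeatureMatrix(_WORKED_EXAMPLE.copy(), _WORKED_EXAMPLE_LABELS.copy())


@dataclass(frozen=True)
class TabularSpec:
    """Two-class Gaussian tabular benchmark.

    n samples, d features, of which ``k_informative`` carry class signal
    at separation ``effect`` (difference of class means, in SD units);
    ``class_balance`` is the fraction of class-1 samples.
    """

    n: int = 200
    d: int = 30
    k_informative: int = 5
    effect: float = 1.5
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n < 2 or self.d < 1:
            raise ValueError("need n >= 2 samples and d >= 1 features")
        if not 0 <= self.k_informative <= self.d:
            raise ValueError("k_informative must lie in [0, d]")
        if self.effect < 0:
            raise ValueError("effect size must be >= 0")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must be in (0, 1)")


def generate_tabular(spec: TabularSpec) -> Tuple[FeatureMatrix, Set[int]]:
    """Draw a tabular benchmark; returns (matrix, informative index set).

    Informative columns are class-conditional N(+-effect/2, 1); the rest
    standard normal independent of class. The informative columns are
    chosen uniformly without replacement.
    """
    rng = np.random.default_rng(spec.seed)
    n1 = int(round(spec.n * spec.class_balance))
    n1 = min(max(n1, 1), spec.n - 1)  # both classes present
    y = np.array([1] * n1 + [0] * (spec.n - n1))
    rng.shuffle(y)
    X = rng.standard_normal((spec.n, spec.d))
    informative = set(rng.choice(spec.d, size=spec.k_informative,
                                 replace=False).tolist())
    shift = spec.effect / 2.0
    for j in informative:
        X[:, j] += np.where(y == 1, shift, -shift)
    return FeatureMatrix(X, y), informative


@dataclass(frozen=True)
class SignalSpec:
    """Epoched oscillatory benchmark with planted band-power modulation.

    Class-1 trials add a band-limited oscillation of amplitude ``snr``
    (relative to unit background noise SD) on ``signal_channels``.
    """

    n_trials: int = 60
    n_channels: int = 8
    n_times: int = 320
    fs: float = 160.0
    signal_channels: tuple = (0, 1)
    band: Tuple[float, float] = (8.0, 12.0)
    snr: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if any(c < 0 or c >= self.n_channels for c in self.signal_channels):
            raise ValueError("signal_channels must lie in [0, n_channels)")
        low, high = self.band
        if not 0 < low < high < self.fs / 2:
            raise ValueError("band must lie inside the Nyquist range")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if self.n_trials < 2 or self.n_channels < 1 or self.n_times < 8:
            raise ValueError("degenerate epoch dimensions")


def _background_noise(rng: np.random.Generator, shape, n_times: int) -> np.ndarray:
    """1/f-ish background: cumulative-summed white noise, re-centered and
    lightly high-passed (first-difference blend) then scaled to unit SD."""
    white = rng.standard_normal(shape + (n_times,))
    brown = np.cumsum(white, axis=-1)
    brown -= brown.mean(axis=-1, keepdims=True)
    x = 0.7 * brown + 0.3 * white
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def generate_signals(spec: SignalSpec) -> EpochSet:
    """Draw an epoched benchmark; ground truth is in the spec itself."""
    rng = np.random.default_rng(spec.seed)
    n1 = spec.n_trials // 2
    labels = np.array([1] * n1 + [0] * (spec.n_trials - n1))
    rng.shuffle(labels)
    data = _background_noise(rng, (spec.n_trials, spec.n_channels),
                             spec.n_times)
    t = np.arange(spec.n_times) / spec.fs
    f0 = 0.5 * (spec.band[0] + spec.band[1])  # band-centre oscillation
    for i in np.flatnonzero(labels == 1):
        for c in spec.signal_channels:
            phase = rng.uniform(0, 2 * np.pi)
            data[i, c] += spec.snr * np.sin(2 * np.pi * f0 * t + phase)
    return EpochSet(data, spec.fs, labels)
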