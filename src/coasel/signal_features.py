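"""EEG-style preprocessing and feature extraction.

Turns epoched multichannel signals (trials x channels x time) into the
n x d feature matrix the selectors operate on. Provides per-channel
normalization (z-score default, min-max alternative), zero-phase
band-pass filtering, time-domain moments, Welch band power, and common
spatial patterns (CSP).

Defaults target motor-imagery EEG: band-pass 8-30 Hz (mu + beta),
canonical PSD bands (delta 1-4, theta 4-8, alpha 8-13, beta 13-30 Hz),
Welch segments of 1 s with 50% overlap, and 3 CSP filter pairs.
Normalization statistics are computed per trial, per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import scipy.linalg
import scipy.signal

from .encoding import FeatureMatrix

__all__ = [
    "EpochSet",
    "CSPFilters",
    "DEFAULT_BANDS",
    "zscore_normalize",
    "minmax_normalize",
    "bandpass_filter",
    "time_domain_features",
    "bandpower_features",
    "csp_fit",
    "csp_transform",
    "build_feature_matrix",
]

#: canonical EEG bands in Hz
DEFAULT_BANDS = [("delta", 1.0, 4.0), ("theta", 4.0, 8.0),
                 ("alpha", 8.0, 13.0), ("beta", 13.0, 30.0)]


@dataclass
class EpochSet:
    """Epoched signals: trials x channels x time, with sampling rate and labels."""

    data: np.ndarray
    fs: float
    labels: np.ndarray
    channel_names: Optional[List[str]] = None

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x time")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        labels = np.asarray(self.labels).astype(int)
        if labels.shape != (data.shape[0],):
            raise ValueError("one label per trial required")
        if self.channel_names is None:
            self.channel_names = [f"ch{c + 1}" for c in range(data.shape[1])]
        elif len(self.channel_names) != data.shape[1]:
            raise ValueError("channel_names length must equal channel count")
        self.data = data
        self.labels = labels

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]


@dataclass(frozen=True)
class CSPFilters:
    """2m x C spatial filters, m eigenvectors from each end of the spectrum.

    ``eigenvalues`` are the class-1 variance shares of each retained
    component under the composite-covariance whitening constraint, so the
    class-2 share of component k is ``1 - eigenvalues[k]``.
    """

    projection: np.ndarray
    eigenvalues: np.ndarray
    classes: tuple

    @property
    def m(self) -> int:
        return self.projection.shape[0] // 2


def _per_channel(epochs: EpochSet, fn) -> EpochSet:
    out = np.empty_like(epochs.data)
    for i in range(epochs.n_trials):
        for c in range(epochs.n_channels):
            out[i, c] = fn(epochs.data[i, c])
    return EpochSet(out, epochs.fs, epochs.labels, list(epochs.channel_names))


def zscore_normalize(epochs: EpochSet) -> EpochSet:
    """Per trial, per channel: subtract the mean, divide by the population SD.

    Channels with zero deviation map to all-zeros.
    """
    if epochs.n_times < 2:
        raise ValueError("z-score normalization needs >=2 samples per channel")

    def z(x):
        mu = x.mean()
        sigma = x.std()  # population form, divisor n
        return (x - mu) / sigma if sigma > 0 else np.zeros_like(x)

    return _per_channel(epochs, z)


def minmax_normalize(epochs: EpochSet) -> EpochSet:
    """Per trial, per channel: map the range onto [0, 1]; constants to 0."""

    def mm(x):
        lo, hi = x.min(), x.max()
        return (x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)

    return _per_channel(epochs, mm)


def bandpass_filter(epochs: EpochSet, low_hz: float, high_hz: float,
                    order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass applied per channel."""
    nyq = epochs.fs / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(f"band ({low_hz}, {high_hz}) Hz must lie inside "
                         f"(0, {nyq}) Hz")
    sos = scipy.signal.butter(order, [low_hz, high_hz], btype="bandpass",
                              fs=epochs.fs, output="sos")
    out = scipy.signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return EpochSet(out, epochs.fs, epochs.labels, list(epochs.channel_names))


def time_domain_features(epochs: EpochSet) -> np.ndarray:
    """Per trial, per channel: mean, population variance, skewness.

    Skewness is the third standardized moment, defined as 0 for
    zero-variance channels. Features are concatenated channel-major:
    (ch1 mean, ch1 var, ch1 skew, ch2 mean, ...).
    """
    X = epochs.data
    mean = X.mean(axis=-1)
    var = X.var(axis=-1)
    centered = X - mean[..., None]
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(var > 0,
                        (centered ** 3).mean(axis=-1) / np.power(var, 1.5,
                            out=np.ones_like(var), where=var > 0),
                        0.0)
    stacked = np.stack([mean, var, skew], axis=-1)  # trials x ch x 3
    return stacked.reshape(epochs.n_trials, -1)


def _time_domain_names(epochs: EpochSet) -> List[str]:
    return [f"{ch}_{stat}" for ch in epochs.channel_names
            for stat in ("mean", "var", "skew")]


def bandpower_features(epochs: EpochSet,
                       bands: Sequence[Tuple[float, float]]) -> np.ndarray:
    """Integrated Welch PSD per trial, channel, and band (trapezoid rule)."""
    nyq = epochs.fs / 2.0
    for low, high in bands:
        if not 0 <= low < high <= nyq:
            raise ValueError(f"band ({low}, {high}) Hz outside (0, {nyq}] Hz")
    nperseg = min(int(epochs.fs), epochs.n_times)  # 1 s segments
    freqs, psd = scipy.signal.welch(epochs.data, fs=epochs.fs,
                                    nperseg=nperseg,
                                    noverlap=nperseg // 2, axis=-1)
    feats = []
    for low, high in bands:
        sel = (freqs >= low) & (freqs <= high)
        feats.append(np.trapezoid(psd[..., sel], freqs[sel], axis=-1))
    # trials x ch x band, channel-major
    return np.stack(feats, axis=-1).reshape(epochs.n_trials, -1)


def _bandpower_names(epochs: EpochSet,
                     bands: Sequence[Tuple[float, float]]) -> List[str]:
    return [f"{ch}_bp_{low:g}_{high:g}" for ch in epochs.channel_names
            for (low, high) in bands]


def _class_mean_covariance(X: np.ndarray) -> np.ndarray:
    """Average of trace-normalized per-trial channel covariances."""
    covs = []
    for trial in X:
        C = trial @ trial.T
        tr = np.trace(C)
        covs.append(C / tr if tr > 0 else C)
    return np.mean(covs, axis=0)


def csp_fit(epochs: EpochSet, m: int = 3) -> CSPFilters:
    """Fit common spatial patterns for a two-class epoch set.

    Solves the generalized eigenproblem ``C1 w = lambda (C1 + C2) w`` on
    class-average trace-normalized covariances (diagonal ridge 1e-8 of
    the trace guards rank deficiency) and keeps the m eigenvectors from
    each end of the spectrum — the directions maximizing the variance
    ratio between the classes. For every retained component the
    whitening identity ``lambda_k^(1) + lambda_k^(2) = 1`` holds.
    """
    classes = np.unique(epochs.labels)
    if classes.size != 2:
        raise ValueError("CSP requires exactly 2 classes")
    if 2 * m > epochs.n_channels:
        raise ValueError("2*m filters cannot exceed the channel count")
    C1 = _class_mean_covariance(epochs.data[epochs.labels == classes[0]])
    C2 = _class_mean_covariance(epochs.data[epochs.labels == classes[1]])
    comp = C1 + C2
    comp = comp + 1e-8 * np.trace(comp) / comp.shape[0] * np.eye(comp.shape[0])
    eigvals, eigvecs = scipy.linalg.eigh(C1, comp)
    order = np.argsort(eigvals)[::-1]  # class-1-dominant first
    keep = np.concatenate([order[:m], order[-m:]])
    W = eigvecs[:, keep].T
    return CSPFilters(projection=W, eigenvalues=eigvals[keep],
                      classes=tuple(classes))


def csp_transform(epochs: EpochSet, filters: CSPFilters) -> np.ndarray:
    """Log variance share of each CSP component, per trial.

    Variance shares are floored at 1e-12 before the log so zero-variance
    trials stay finite.
    """
    W = filters.projection
    if W.shape[1] != epochs.n_channels:
        raise ValueError("filter width does not match channel count")
    feats = np.empty((epochs.n_trials, W.shape[0]))
    for i, trial in enumerate(epochs.data):
        Z = W @ trial
        var = Z.var(axis=-1)
        total = var.sum()
        share = var / total if total > 0 else np.zeros_like(var)
        feats[i] = np.log(np.maximum(share, 1e-12))
    return feats


@dataclass
class FeatureSpec:
    """Which feature families to extract, in declared order."""

    families: List[str] = field(default_factory=lambda: ["time", "bandpower"])
    bands: List[Tuple[float, float]] = field(
        default_factory=lambda: [(lo, hi) for _, lo, hi in DEFAULT_BANDS])
    csp_pairs: int = 3


def build_feature_matrix(epochs: EpochSet,
                         feature_spec: Optional[FeatureSpec] = None) -> FeatureMatrix:
    """Concatenate the requested feature families into a FeatureMatrix.

    Families: ``time`` (mean/var/skew per channel), ``bandpower``
    (Welch band power per channel and band), ``csp`` (log variance
    shares of CSP components, fitted on these epochs' labels).
    """
    spec = feature_spec if feature_spec is not None else FeatureSpec()
    if not spec.families:
        raise ValueError("feature spec must request at least one family")
    blocks, names = [], []
    for family in spec.families:
        if family == "time":
            blocks.append(time_domain_features(epochs))
            names.extend(_time_domain_names(epochs))
        elif family == "bandpower":
            blocks.append(bandpower_features(epochs, spec.bands))
            names.extend(_bandpower_names(epochs, spec.bands))
        elif family == "csp":
            filters = csp_fit(epochs, m=spec.csp_pairs)
            blocks.append(csp_transform(epochs, filters))
            names.extend(f"csp{k + 1}" for k in range(2 * spec.csp_pairs))
        else:
            raise ValueError(f"unknown feature family {family!r}")
    return FeatureMatrix(np.hstack(blocks), epochs.labels, names)
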