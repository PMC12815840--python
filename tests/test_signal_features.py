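import numpy as np
import pytest

from coasel import (EpochSet, bandpass_filter, bandpower_features,
                    build_feature_matrix, csp_fit, csp_transform,
                    minmax_normalize, time_domain_features, zscore_normalize)
from coasel.signal_features import FeatureSpec, _class_mean_covariance


def make_epochs(data, fs=100.0, labels=None):
    data = np.asarray(data, dtype=float)
    labels = labels if labels is not None else [0] * data.shape[0]
    return EpochSet(data, fs, labels)


def tone_epochs(freq, fs=160.0, seconds=4.0, n_trials=2, amp=1.0):
    t = np.arange(int(fs * seconds)) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    data = np.tile(x, (n_trials, 1, 1))
    return EpochSet(data, fs, [0, 1][:n_trials] + [0] * max(0, n_trials - 2))


def test_epochset_validation():
    with pytest.raises(ValueError):
        EpochSet(np.zeros((2, 3)), 100.0, [0, 1])
    with pytest.raises(ValueError):
        EpochSet(np.zeros((2, 3, 4)), 0.0, [0, 1])
    with pytest.raises(ValueError):
        EpochSet(np.zeros((2, 3, 4)), 100.0, [0])


def test_zscore_normalize():
    ep = zscore_normalize(make_epochs([[[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]]))
    ch = ep.data[0, 0]
    assert ch.mean() == pytest.approx(0.0, abs=1e-9)
    assert ch.std() == pytest.approx(1.0, abs=1e-9)  # population SD
    np.testing.assert_array_equal(ep.data[0, 1], [0, 0, 0])  # constant -> 0
    again = zscore_normalize(ep)
    np.testing.assert_allclose(again.data, ep.data, atol=1e-12)  # idempotent


def test_minmax_normalize():
    ep = minmax_normalize(make_epochs([[[2.0, 4.0, 6.0], [7.0, 7.0, 7.0]]]))
    np.testing.assert_allclose(ep.data[0, 0], [0.0, 0.5, 1.0])
    np.testing.assert_array_equal(ep.data[0, 1], [0, 0, 0])
    rng = np.random.default_rng(0)
    ep2 = minmax_normalize(make_epochs(rng.standard_normal((3, 2, 50))))
    assert ep2.data.min() >= 0.0 and ep2.data.max() <= 1.0


def test_bandpass_passband_and_stopband():
    passed = bandpass_filter(tone_epochs(10.0), 8, 30)
    assert passed.data.std() / tone_epochs(10.0).data.std() > 0.9
    stopped = bandpass_filter(tone_epochs(2.0), 8, 30)
    assert tone_epochs(2.0).data.std() / stopped.data.std() >= 10.0
    zero = bandpass_filter(make_epochs(np.zeros((1, 1, 200))), 8, 30)
    np.testing.assert_allclose(zero.data, 0.0, atol=1e-12)


def test_bandpass_rejects_bad_band():
    with pytest.raises(ValueError):
        bandpass_filter(tone_epochs(10.0, fs=100.0), 8, 60)  # above Nyquist


def test_time_domain_features():
    ep = make_epochs([[[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]]])
    feats = time_domain_features(ep)
    np.testing.assert_allclose(feats[0], [2.0, 2 / 3, 0.0, 4.0, 0.0, 0.0])
    # mirrored data: means negate, variances equal, skewness negates
    rng = np.random.default_rng(1)
    x = rng.standard_normal((2, 1, 100)) ** 3  # skewed
    f_pos = time_domain_features(make_epochs(x))
    f_neg = time_domain_features(make_epochs(-x))
    np.testing.assert_allclose(f_neg[:, 0], -f_pos[:, 0])
    np.testing.assert_allclose(f_neg[:, 1], f_pos[:, 1])
    np.testing.assert_allclose(f_neg[:, 2], -f_pos[:, 2])


def test_bandpower_tone_concentration():
    bp = bandpower_features(tone_epochs(10.0), [(8, 12), (20, 30)])
    assert bp[0, 0] >= 100 * bp[0, 1]
    assert np.all(bp >= 0)
    zeros = bandpower_features(make_epochs(np.zeros((1, 1, 320)), fs=160.0),
                               [(8, 12)])
    np.testing.assert_allclose(zeros, 0.0, atol=1e-20)


def test_bandpower_white_noise_flatness():
    rng = np.random.default_rng(2)
    powers = []
    for _ in range(20):
        ep = make_epochs(rng.standard_normal((1, 1, 1600)), fs=160.0)
        powers.append(bandpower_features(ep, [(10, 20), (30, 40)])[0])
    powers = np.array(powers)
    diff = powers[:, 0] - powers[:, 1]
    se = diff.std(ddof=1) / np.sqrt(len(diff))
    assert abs(diff.mean()) < 3 * se


def test_bandpower_rejects_band_above_nyquist():
    with pytest.raises(ValueError):
        bandpower_features(tone_epochs(10.0, fs=100.0), [(40, 60)])


def planted_variance_epochs(seed=0, n=40, C=4, T=200, factor=3.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, C, T))
    y = np.tile([0, 1], n // 2)
    X[y == 1, 0, :] *= factor
    return EpochSet(X, 100.0, y)


def test_csp_planted_variance_recovery():
    ep = planted_variance_epochs()
    filters = csp_fit(ep, m=1)
    # the class-1-dominant filter (smallest eigenvalue end) peaks on the
    # channel whose variance was inflated for class 1
    w = filters.projection[np.argmin(filters.eigenvalues)]
    assert np.argmax(np.abs(w)) == 0


def test_csp_whitening_identity():
    ep = planted_variance_epochs(seed=3)
    filters = csp_fit(ep, m=2)
    C0 = _class_mean_covariance(ep.data[ep.labels == 0])
    C1 = _class_mean_covariance(ep.data[ep.labels == 1])
    for w in filters.projection:
        lam0 = w @ C0 @ w
        lam1 = w @ C1 @ w
        assert lam0 + lam1 == pytest.approx(1.0, abs=1e-6)


def test_csp_symmetric_classes_near_half():
    rng = np.random.default_rng(7)
    X = rng.standard_normal((400, 3, 300))
    ep = EpochSet(X, 100.0, np.tile([0, 1], 200))
    filters = csp_fit(ep, m=1)
    assert np.allclose(filters.eigenvalues, 0.5, atol=0.05)


def test_csp_rejects_more_than_two_classes():
    ep = EpochSet(np.random.default_rng(0).standard_normal((3, 2, 20)),
                  100.0, [0, 1, 2])
    with pytest.raises(ValueError):
        csp_fit(ep, m=1)


def test_csp_transform_separates_and_is_deterministic():
    ep = planted_variance_epochs(seed=5)
    filters = csp_fit(ep, m=1)
    feats = csp_transform(ep, filters)
    k = int(np.argmin(filters.eigenvalues))
    a, b = feats[ep.labels == 1, k], feats[ep.labels == 0, k]
    pooled_sd = np.sqrt((a.var() + b.var()) / 2)
    assert abs(a.mean() - b.mean()) >= pooled_sd
    # duplicate trial -> identical features; zero trial stays finite
    dup = EpochSet(np.vstack([ep.data[:1], ep.data[:1],
                              np.zeros_like(ep.data[:1])]),
                   ep.fs, [0, 1, 0])
    f2 = csp_transform(dup, filters)
    np.testing.assert_array_equal(f2[0], f2[1])
    assert np.all(np.isfinite(f2[2]))


def test_build_feature_matrix_bookkeeping():
    rng = np.random.default_rng(0)
    ep = EpochSet(rng.standard_normal((5, 2, 160)), 160.0,
                  [0, 1, 0, 1, 0])
    F_time = build_feature_matrix(ep, FeatureSpec(families=["time"]))
    assert (F_time.n, F_time.d) == (5, 6)  # 3 moments x 2 channels
    one_band = build_feature_matrix(
        ep, FeatureSpec(families=["bandpower"], bands=[(8, 12)]))
    two_bands = build_feature_matrix(
        ep, FeatureSpec(families=["bandpower"], bands=[(8, 12), (13, 30)]))
    assert two_bands.d - one_band.d == ep.n_channels
    with pytest.raises(ValueError):
        build_feature_matrix(ep, FeatureSpec(families=[]))


def test_feature_names_roundtrip(tmp_path):
    rng = np.random.default_rng(0)
    ep = EpochSet(rng.standard_normal((4, 2, 160)), 160.0, [0, 1, 0, 1])
    F = build_feature_matrix(ep, FeatureSpec(families=["time", "bandpower"],
                                             bands=[(8, 12)]))
    path = tmp_path / "F.csv"
    F.to_csv(path, label_column="label")
    from coasel import FeatureMatrix
    back = FeatureMatrix.read_csv(path, label_column="label")
    assert back.feature_names == F.feature_names
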