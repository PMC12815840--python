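import numpy as np
import pytest

from coasel import worked_example_fixture


@pytest.fixture
def demo():
    """The hand-checkable 5x6 two-class matrix with labels [1,1,0,0,0]."""
    return worked_example_fixture()


def brute_force_loocv_1nn(X, y):
    """Independent LOOCV 1-NN oracle: plain loops, explicit min search,
    ties to the lowest training-row index."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    correct = 0
    for i in range(n):
        best_dist, best_j = None, None
        for j in range(n):
            if j == i:
                continue
            dist = sum((X[i, k] - X[j, k]) ** 2 for k in range(X.shape[1])) ** 0.5
            if best_dist is None or dist < best_dist:
                best_dist, best_j = dist, j
        correct += int(y[best_j] == y[i])
    return correct / n
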