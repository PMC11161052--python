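import numpy as np
import pytest

from sillyputty import (
    ClusterLabels,
    DistanceMatrix,
    FeatureMatrix,
    euclidean_distances,
    validate_distance_matrix,
)


@pytest.fixture
def line4() -> DistanceMatrix:
    """Four points on a line at 0, 1, 10, 11 (two tight pairs)."""
    pos = np.array([0.0, 1.0, 10.0, 11.0])
    return validate_distance_matrix(np.abs(np.subtract.outer(pos, pos)))


def make_blobs(n: int, k: int, seed: int, sep: float = 12.0, dim: int = 2):
    """Well-separated isotropic Gaussian blobs with truth labels."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(scale=sep, size=(k, dim))
    truth = np.arange(n) % k
    rng.shuffle(truth)
    X = centers[truth] + rng.normal(scale=0.5, size=(n, dim))
    fm = FeatureMatrix(X)
    return fm, ClusterLabels(truth, fm.sample_ids), euclidean_distances(fm)


@pytest.fixture
def blobs3():
    """60 samples in 3 well-separated blobs plus their distance matrix."""
    return make_blobs(60, 3, seed=7)


def random_instance(rng: np.random.Generator, n_max: int = 30, k_max: int = 5):
    """A random distance matrix and labeling with k >= 2 nonempty clusters."""
    n = int(rng.integers(4, n_max + 1))
    k = int(rng.integers(2, min(k_max, n // 2) + 1))
    pts = rng.normal(size=(n, 3))
    D = euclidean_distances(FeatureMatrix(pts))
    labels = np.concatenate([np.arange(k), rng.integers(0, k, size=n - k)])
    rng.shuffle(labels)
    return D, ClusterLabels(labels)
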