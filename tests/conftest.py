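import numpy as np
import pytest

import densitycloud as dc


@pytest.fixture
def tiny_ds() -> dc.GroupedDataset:
    """6 rows, 2 variables, groups of 3: the smallest legal dataset."""
    values = np.array([[0.0, 1.0], [1.0, 2.0], [2.0, 0.0],
                       [5.0, 5.0], [6.0, 4.0], [7.0, 6.0]])
    labels = np.array(["B", "B", "B", "A", "A", "A"])
    return dc.GroupedDataset(values=values, group_labels=labels,
                             var_names=("x", "y"), group_names=("B", "A"))


@pytest.fixture
def gauss_ds() -> dc.GroupedDataset:
    """Two d=3 Gaussian groups with a modest centroid shift (n=300/group)."""
    spec = dc.ScenarioSpec(n_per_group=300, d=3, centroid_shift=[0.8, 0, 0],
                           seed=7)
    return dc.gaussian_groups(spec)


@pytest.fixture
def identical_ds() -> dc.GroupedDataset:
    """Groups A and B containing exactly the same 40 rows."""
    rng = np.random.default_rng(5)
    X = rng.standard_normal((40, 2))
    values = np.vstack([X, X])
    labels = np.array(["B"] * 40 + ["A"] * 40)
    return dc.GroupedDataset(values=values, group_labels=labels,
                             var_names=("x", "y"), group_names=("B", "A"))


def brute_force_sq_dist_sums(sample: np.ndarray, coords: np.ndarray,
                             k: int) -> np.ndarray:
    """Independent oracle: sorted pairwise distances, no spatial index."""
    from scipy.spatial.distance import cdist
    d2 = np.sort(cdist(coords, sample, metric="sqeuclidean"), axis=1)
    return d2[:, :k].sum(axis=1)


def brute_force_knn_density(sample: np.ndarray, coords: np.ndarray,
                            k: int) -> np.ndarray:
    """Direct evaluation of the k-NN density formula via brute force."""
    import math
    n, d = sample.shape
    sums = brute_force_sq_dist_sums(sample, coords, k)
    num = sum(j ** (2.0 / d) for j in range(1, k + 1))
    vd = math.pi ** (d / 2) / math.gamma(d / 2 + 1)
    return num / (n * vd * sums ** (d / 2))
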