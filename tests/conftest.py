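import numpy as np
import pytest

from metafs.objective import ClassifierId, ObjectiveConfig, ObjectiveId


@pytest.fixture(scope="session")
def separable_dataset():
    """Tiny linearly separable imbalanced dataset (minority class 1).

    Two informative dimensions with a wide class gap and one pure-noise
    dimension; any reasonable classifier reaches recall ~1 on it.
    """
    rng = np.random.default_rng(1234)
    n_min, n_maj = 45, 105
    y = np.r_[np.ones(n_min, dtype=int), np.zeros(n_maj, dtype=int)]
    X = rng.normal(size=(n_min + n_maj, 3))
    X[:, :2] += 8.0 * y[:, None]
    perm = rng.permutation(len(y))
    return X[perm], y[perm]


@pytest.fixture
def knn_objective_cfg():
    return ObjectiveConfig(objective_id=ObjectiveId.OF1,
                           classifier_id=ClassifierId.KNN, seed=7)


@pytest.fixture(scope="session")
def hidden_mask():
    return np.random.default_rng(0).integers(0, 2, 15)


@pytest.fixture(scope="session")
def hamming_objective(hidden_mask):
    def objective(mask):
        return float(np.sum(np.asarray(mask) != hidden_mask))

    return objective
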