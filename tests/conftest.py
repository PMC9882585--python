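import numpy as np
import pytest

from enhancekit.data import Dataset
from enhancekit.synthetic import SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> Dataset:
    """Desk-scale analogue of the default cohort: 4 imbalanced classes,
    300 edge-like features, near-chance baseline."""
    spec = SyntheticSpec(
        class_sizes=(40, 16, 15, 13), n_features=300, separation=3.0, seed=0
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def separable_toy() -> Dataset:
    """Two well-separated Gaussian classes in 2-D (trivially learnable)."""
    rng = np.random.default_rng(42)
    n = 20
    X = np.vstack([
        rng.normal([-4.0, -4.0], 0.3, size=(n, 2)),
        rng.normal([4.0, 4.0], 0.3, size=(n, 2)),
    ])
    y = np.array([0] * n + [1] * n)
    return Dataset(X=X, y=y)


@pytest.fixture(scope="session")
def overlap_toy() -> Dataset:
    """Two heavily overlapping Gaussian classes (baseline CV accuracy near
    one half), n=40, 2 features."""
    rng = np.random.default_rng(7)
    n = 20
    X = np.vstack([
        rng.normal([-0.1, 0.0], 1.0, size=(n, 2)),
        rng.normal([0.1, 0.0], 1.0, size=(n, 2)),
    ])
    y = np.array([0] * n + [1] * n)
    return Dataset(X=X, y=y)


@pytest.fixture(scope="session")
def multiclass_toy() -> Dataset:
    """Four moderately separated classes in 10-D; enough signal that every
    training fold sees all classes."""
    rng = np.random.default_rng(3)
    sizes = (15, 12, 12, 11)
    means = rng.normal(0, 1.5, size=(4, 10))
    X = np.vstack([rng.normal(means[k], 1.0, size=(s, 10)) for k, s in enumerate(sizes)])
    y = np.concatenate([np.full(s, k) for k, s in enumerate(sizes)])
    return Dataset(X=X, y=y)
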