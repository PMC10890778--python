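import numpy as np
import pytest

from kncfs import (
    LabeledDataset,
    SyntheticSpec,
    make_dataset,
    standardize,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_labeled(rng, n, d, n_classes=2):
    """Random standard-normal dataset with cyclic labels."""
    X = rng.standard_normal((n, d))
    y = np.arange(n) % n_classes
    return LabeledDataset(X=X, y=y)


@pytest.fixture
def small_dataset(rng):
    return random_labeled(rng, n=12, d=5)


@pytest.fixture
def separable_dataset():
    """Feature 0 separates the two classes with a wide gap; rest is noise."""
    g = np.random.default_rng(7)
    n = 40
    y = np.arange(n) % 2
    X = g.standard_normal((n, 5)) * 0.2
    X[:, 0] += np.where(y == 0, -3.0, 3.0)
    return LabeledDataset(X=X, y=y)


def collinear_block_dataset(seed, n=60, blocks=3, block_size=8, rho=0.98):
    """Blocks of mutually correlated features; no class signal."""
    spec = SyntheticSpec(
        n=n,
        d_rel=0,
        n_noise=0,
        block_spec=[(block_size, rho)] * blocks,
        seed=seed,
    )
    ds, _ = make_dataset(spec)
    return standardize(ds)
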