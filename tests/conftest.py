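import numpy as np
import pytest

from go2pls import GroupStructure


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_xy(rng):
    """A generic full-rank two-block instance (30 samples, 40 x 20 features)."""
    X = rng.standard_normal((30, 40))
    Y = rng.standard_normal((30, 20))
    return X, Y


@pytest.fixture
def mixed_groups():
    """Ten groups of mixed sizes partitioning 40 features."""
    sizes = [8, 6, 6, 5, 5, 4, 3, 1, 1, 1]
    labels = []
    for j, s in enumerate(sizes):
        labels += [f"g{j}"] * s
    return GroupStructure.from_labels(labels)
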