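import numpy as np
import pytest

import drivermut as dm


@pytest.fixture(scope="session")
def default_cfg():
    return dm.default_config()


@pytest.fixture(scope="session")
def small_dataset():
    """A small mechanistic dataset with substitution + annotated signal."""
    ds, truth = dm.simulate_dataset(
        dm.SimConfig(n_driver=50, n_passenger=50, effect_size=2.0, seed=42)
    )
    return ds, truth


@pytest.fixture(scope="session")
def tabular():
    """Fast planted-feature table: 200 samples, 5 of 100 informative at 4σ."""
    fm, labels, truth = dm.simulate_feature_table(
        n_samples=200, n_features=100, n_informative=5, effect_size=4.0, seed=7
    )
    return fm, labels, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def forest_factory(seed=0, n_trees=10):
    return lambda: dm.RotationForest(dm.RotationSpec(n_trees=n_trees, seed=seed))
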