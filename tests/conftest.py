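import numpy as np
import pytest

import redstartcalls as rc
from redstartcalls.features import batch_features, prune_correlated


@pytest.fixture(scope="session")
def default_population():
    """One default synthetic population (36 birds x 5 calls), seed 1."""
    cfg = rc.PopulationConfig(seed=1)
    clips, manifest = rc.generate_clips(cfg)
    return cfg, clips, manifest


@pytest.fixture(scope="session")
def feature_table(default_population):
    _, clips, _ = default_population
    table, errors = batch_features(clips)
    assert not errors
    return table


@pytest.fixture(scope="session")
def pruned_table(feature_table):
    pruned, _ = prune_correlated(feature_table)
    return pruned


@pytest.fixture(scope="session")
def similarity_result(pruned_table):
    """A moderately sized proximity fit shared across similarity tests."""
    return rc.ProximityForest(pruned_table, n_trees=500).fit(seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
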