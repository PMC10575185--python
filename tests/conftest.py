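import pandas as pd
import numpy as np
import pytest

from maldisort.binning import FeatureTable
from maldisort.simulate import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def easy_dataset(tmp_path_factory):
    """Full-size seeded easy-preset dataset (48+48 spots per role per mode)."""
    out = tmp_path_factory.mktemp("easy")
    cfg = SimConfig(seed=42, preset="easy")
    manifest, manifest_path = generate_dataset(cfg, out)
    return cfg, manifest, manifest_path


@pytest.fixture(scope="session")
def hard_dataset(tmp_path_factory):
    """Full-size seeded hard-preset dataset."""
    out = tmp_path_factory.mktemp("hard")
    cfg = SimConfig(seed=42, preset="hard")
    manifest, manifest_path = generate_dataset(cfg, out)
    return cfg, manifest, manifest_path


@pytest.fixture(scope="session")
def small_sim_config():
    """A light simulation config for unit tests (small proteome, few spots)."""
    return SimConfig(seed=7, preset="easy", n_proteins=400,
                     spots_per_class_train=4, spots_per_class_score=4)


def random_binary_table(n_per_class=48, n_features=200, seed=0, planted=True):
    """A synthetic binary feature table, optionally with a planted
    class-separating feature.

    Built from raw arrays rather than the simulator: classifier unit tests
    should not depend on the generative model.
    """
    rng = np.random.default_rng(seed)
    X = (rng.random((2 * n_per_class, n_features)) < 0.2).astype(float)
    y = ["positive"] * n_per_class + ["negative"] * n_per_class
    if planted:
        X[:n_per_class, 0] = 1.0
        X[n_per_class:, 0] = 0.0
    idx = pd.Index([f"s{i:03d}" for i in range(2 * n_per_class)], name="spot_id")
    data = pd.DataFrame(X, index=idx, columns=[f"b{j}" for j in range(n_features)])
    return FeatureTable(data=data, labels=pd.Series(y, index=idx, name="label"),
                        encoding="binary")
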