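import numpy as np
import pandas as pd
import pytest

from xplatclass import SimulationConfig, generate_paired_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_scenario():
    """A fast four-subtype paired dataset with a clear class signal."""
    cfg = SimulationConfig(
        n_features=80,
        n_informative_per_class=4,
        n_tumor_per_class=12,
        n_test_per_class=5,
        effect_size=2.0,
        seed=11,
    ).validate()
    return generate_paired_dataset(cfg)


def random_matrix(rng, n_features=10, n_samples=8, positive=False):
    values = rng.normal(size=(n_features, n_samples))
    if positive:
        values = np.exp(values) + 1.0
    return pd.DataFrame(
        values,
        index=[f"f{i:03d}" for i in range(n_features)],
        columns=[f"s{j:03d}" for j in range(n_samples)],
    )
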