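import numpy as np
import pandas as pd
import pytest

from grccax import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-effect dataset shared by read-only tests."""
    cfg = SimulationConfig(
        n_genes=300,
        module_sizes=(50, 50, 50),
        n_per_group=(20, 20, 20, 20),
        effect_modules=(1,),
        effect_size=0.8,
        seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_counts():
    return pd.DataFrame(
        [[10, 10, 10, 10, 10], [10, 10, 10, 10, 9], [0, 0, 0, 0, 0]],
        index=["a", "b", "c"],
        columns=[f"s{i}" for i in range(5)],
    )
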