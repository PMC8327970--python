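import numpy as np
import pandas as pd
import pytest

from flucasym import SyntheticConfig, load_table2_fixture, simulate_dataset


@pytest.fixture(scope="session")
def table2():
    return load_table2_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def toy_records():
    """One individual, one trait, L/R, 2 replicates — minimal valid CSV body."""
    return pd.DataFrame(
        {
            "individual_id": ["a1"] * 4,
            "sex": ["female"] * 4,
            "tooth": ["MXM1"] * 4,
            "arcade": ["maxilla"] * 4,
            "tooth_class": ["molar"] * 4,
            "metric": ["length"] * 4,
            "side": ["L", "L", "R", "R"],
            "replicate": [1, 2, 1, 2],
            "value_mm": [10.1, 10.2, 10.3, 10.4],
        }
    )


@pytest.fixture(scope="session")
def simulated_trait_records():
    """A single simulated trait, J=20, M=10, no missingness."""
    cfg = SyntheticConfig(n_individuals=20, n_replicates=10, seed=11)
    return simulate_dataset(cfg, sex="male", tooth="MNM2", metric="breadth")
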