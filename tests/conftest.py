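import numpy as np
import pytest

from tetrasig import composition, simulate


@pytest.fixture(scope="session")
def six_group_dataset():
    """Default survey scenario realised once per session (seed 0)."""
    scenario = simulate.six_group_scenario(master_seed=0)
    records, manifest = simulate.simulate_dataset(scenario)
    return scenario, records, manifest


@pytest.fixture(scope="session")
def six_group_profiles(six_group_dataset):
    _, records, _ = six_group_dataset
    return composition.profile_matrix([(r.id, r.sequence) for r in records])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
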