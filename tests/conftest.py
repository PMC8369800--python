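import numpy as np
import pytest

from hictempo import SimConfig, simulate_contact_map
from hictempo.matrix import ice_balance, merge_replicates, oe_transform


@pytest.fixture(scope="session")
def small_sim():
    """One balanced 300-bin simulated chromosome with truth."""
    cfg = SimConfig(n_bins=300, seed=42)
    reps, truth = simulate_contact_map(cfg)
    merged = merge_replicates(reps)
    bal = ice_balance(merged)
    return cfg, reps, truth, bal


@pytest.fixture(scope="session")
def small_oe(small_sim):
    _, _, _, bal = small_sim
    return oe_transform(bal)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
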