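import numpy as np
import pandas as pd
import pytest

from crossplice import SimulationConfig, simulate_count_table
from crossplice.splicing import EventCountTable


@pytest.fixture
def tiny_table():
    """Two events, two conditions x two replicates, hand-set counts."""
    counts = pd.DataFrame(
        {
            "event_id": ["e1"] * 4 + ["e2"] * 4,
            "sample_id": ["c1", "c2", "k1", "k2"] * 2,
            "long_count": [30, 28, 75, 80, 0, 0, 10, 12],
            "short_count": [10, 12, 25, 20, 50, 48, 40, 38],
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": ["c1", "c2", "k1", "k2"],
            "condition": ["control", "control", "kd", "kd"],
            "replicate": [1, 2, 1, 2],
        }
    )
    return EventCountTable(counts=counts, samples=samples)


@pytest.fixture(scope="session")
def default_sim():
    """One moderate simulation shared by tests that only read it."""
    cfg = SimulationConfig(n_events=400, seed=11)
    table, truth = simulate_count_table(cfg)
    return cfg, table, truth


def rng_psi_groups(seed, n_ctrl=3, n_kd=3, base=50.0, delta=0.0, sd=3.0):
    rng = np.random.default_rng(seed)
    ctrl = np.clip(base + rng.normal(0, sd, n_ctrl), 0, 100)
    kd = np.clip(base + delta + rng.normal(0, sd, n_kd), 0, 100)
    return ctrl, kd
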