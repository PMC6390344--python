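import numpy as np
import pandas as pd
import pytest

from recombscape import SimulationConfig, simulate_population


@pytest.fixture(scope="session")
def small_population():
    """A modest half-sib cohort shared across detection/window tests."""
    cfg = SimulationConfig(
        seed=5,
        n_families=24,
        offspring_per_family=4,
        chromosome_lengths_mb=(30.0, 30.0),
        markers_per_mb=20,
        hotspot_fraction=0.0,
        sex_rate_multiplier=1.0,
    )
    G, ped, truth = simulate_population(cfg)
    return cfg, G, ped, truth


def make_pedigree(rows):
    return pd.DataFrame(rows, columns=["individual", "sire", "dam", "sex"])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
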