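import numpy as np
import pandas as pd
import pytest

import hitseq as hq


@pytest.fixture(scope="session")
def landscape():
    """Default bimodal ground-truth landscape over all 16,384 7-mers."""
    return hq.make_landscape(seed=1)


@pytest.fixture(scope="session")
def truth_table(landscape):
    """Ground-truth K_A,rel (kd_ref/kd) as an AffinityTable."""
    ka = pd.Series(
        landscape.kd_of("UGCAUGU") / landscape.kd,
        index=landscape.variants,
    )
    return hq.AffinityTable.from_series(ka)


@pytest.fixture(scope="session")
def small_config():
    """Light simulation settings for fast unit tests."""
    return hq.SimulationConfig(depth=20_000, error_rate=0.0, seed=7)


@pytest.fixture(scope="session")
def small_run(landscape, small_config):
    """A small simulated experiment: (counts, libraries)."""
    return hq.run_simulation(landscape, small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
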