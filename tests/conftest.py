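import numpy as np
import pytest

from bolustransit import synthetic, tac


@pytest.fixture(scope="session")
def fine_grid():
    return synthetic.default_grid()


@pytest.fixture(scope="session")
def clean_truth():
    """Resting-condition truth with no noise and no recirculation."""
    return synthetic.PhantomTruth(noise_sigma=0.0, recirc_fraction=0.0, seed=0)


@pytest.fixture(scope="session")
def clean_curves(clean_truth, fine_grid):
    return synthetic.simulate_transit(clean_truth, fine_grid)


@pytest.fixture(scope="session")
def pet_scheme():
    return tac.build_framing(tac.PET_DYNAMIC_BLOCKS)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
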