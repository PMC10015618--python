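import numpy as np
import pytest

from mescan.demography import (
    TABLE_DIV,
    TABLE_IM_INTO_A,
    BlockConfig,
    DemographyParams,
)


@pytest.fixture(scope="session")
def im_params() -> DemographyParams:
    """Best-fitting isolation-with-migration history (gene flow into A)."""
    return TABLE_IM_INTO_A


@pytest.fixture(scope="session")
def div_params() -> DemographyParams:
    return TABLE_DIV


@pytest.fixture(scope="session")
def block_config() -> BlockConfig:
    return BlockConfig()


@pytest.fixture(scope="session")
def small_im_tally(im_params, block_config):
    """A modest simulated tally shared by likelihood/inference tests."""
    from mescan.simulate import simulate_block_tallies

    return simulate_block_tallies(im_params, block_config, 20_000, seed=101)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
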