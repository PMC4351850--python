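import numpy as np
import pytest
from hypothesis import settings

from sitsim.campaign import CampaignConfig
from sitsim.genetics import SITImplementation

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_config(**overrides) -> CampaignConfig:
    """A deliberately tiny, fast configuration for unit tests: a small
    habitat (tens of adult females) and short horizons. Desk-scale defaults
    are exercised in the acceptance tests."""
    base = dict(
        implementation=SITImplementation.NONE,
        carrying_capacity=2000.0,
        burn_in_days=20,
        baseline_window_days=10,
        campaign_days=15,
        initial_adults=40,
        replicates=2,
        master_seed=99,
        final_window_days=10,
    )
    base.update(overrides)
    return CampaignConfig(**base)
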