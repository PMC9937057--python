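import numpy as np
import pytest

import climblearn as cl


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_config():
    return cl.ProtocolConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny, well-identified cohort shared by several structural tests."""
    config = cl.ProtocolConfig(group_sizes={"CP": 4, "VP1": 4, "VP2": 5})
    prior = cl.LatentPrior(b_mean=0.08, b_sd=0.02, noise_sd=0.05)
    return cl.generate_dataset(config, prior, seed=7)
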