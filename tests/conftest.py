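import numpy as np
import pytest

from betpl.model import BetplParams, betpl_sample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ref_params():
    """A mid-grid BETPL parameter set used across tests."""
    return BetplParams(mu=1.5, lambda1=0.02, lambda2=0.5, lim_a=0.3)


@pytest.fixture
def ref_sample(ref_params):
    return betpl_sample(ref_params, 5000, seed=7)
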