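import numpy as np
import pytest

from cosmodel import stimgen


@pytest.fixture(scope="session")
def e1_design():
    return stimgen.build_design("E1", rng_seed=7)


@pytest.fixture(scope="session")
def e1_trial(e1_design):
    """One generated trial of the position experiment."""
    return stimgen.sample_trial(e1_design.trials[0], e1_design, rng_seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
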