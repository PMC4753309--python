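import numpy as np
import pytest

from ferromat.config import site_config


@pytest.fixture(scope="session")
def osp():
    return site_config("osp")


@pytest.fixture(scope="session")
def beowulf():
    return site_config("beowulf")


@pytest.fixture(scope="session")
def incubation_times():
    """The slide-deployment schedule: 11 points over 0-70 days."""
    return np.arange(0.0, 71.0, 7.0)
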