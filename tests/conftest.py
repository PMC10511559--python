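import numpy as np
import pytest

from ferrofat.config import default_fat_spectrum, default_protocol


@pytest.fixture(scope="session")
def spectrum():
    return default_fat_spectrum()


@pytest.fixture(scope="session")
def pancreas_protocol():
    return default_protocol("pancreas")


@pytest.fixture(scope="session")
def heart_protocol():
    return default_protocol("heart")


@pytest.fixture
def rng():
    return np.random.default_rng(20230428)
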