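import numpy as np
import pytest

from pcmotion import generate_duncker, generate_johansson, generate_rdk


@pytest.fixture(scope="session")
def johansson_small():
    return generate_johansson(duration=2.0)


@pytest.fixture(scope="session")
def duncker_small():
    return generate_duncker(angular_speed=90.0, duration=4.0)


@pytest.fixture(scope="session")
def rdk_small():
    return generate_rdk(n_dots=20, signal_ratio=0.5, duration=5.0, seed=1234)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
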