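import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from prebcr import get_preset  # noqa: E402


@pytest.fixture(scope="session")
def preset_697():
    return get_preset("697")


@pytest.fixture(scope="session")
def preset_nalm6():
    return get_preset("nalm6")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
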