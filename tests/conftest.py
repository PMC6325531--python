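import numpy as np
import pytest

from trackadapt import SamplingSpec, load_target_patterns


@pytest.fixture(scope="session")
def patterns():
    return load_target_patterns()


@pytest.fixture(scope="session")
def timing():
    return SamplingSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
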