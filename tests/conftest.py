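import numpy as np
import pytest

from whalefmr.synthetic import SyntheticTagConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tag_config():
    """Low-rate sensor config so synthetic-stream tests stay fast."""
    return SyntheticTagConfig(fs_hz=10.0)
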