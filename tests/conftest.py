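import numpy as np
import pytest

from lesionseg.config import NetConfig
from lesionseg.model import build_model

TINY = NetConfig(input_size=64, width_mult=1 / 8, conv4_blocks=2)


@pytest.fixture(scope="session")
def tiny_cfg():
    return TINY


@pytest.fixture(scope="session")
def tiny_model(tiny_cfg):
    """One shared random-init full model (eval mode) for forward-pass tests."""
    model = build_model(tiny_cfg, mode="full", seed=0)
    model.eval()
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
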