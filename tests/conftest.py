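import numpy as np
import pytest

from fruitdet.network import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_cfg():
    """Smallest config that still exercises every architectural piece."""
    return ModelConfig(
        num_classes=1,
        width_mult=0.25,
        stage_channels=(16, 32, 64, 128),
        stage_blocks=(1, 1, 1, 1),
        bifpn_channels=16,
        bifpn_repeats=1,
        regmax=8,
    )
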