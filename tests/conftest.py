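import numpy as np
import pytest

from pmffnet.data import preprocess
from pmffnet.model import ModelConfig, PMFFNet
from pmffnet.phantom import PhantomConfig, generate_phantom


def tiny_model_config(**overrides) -> ModelConfig:
    """Smallest architecture variant that still exercises every component."""
    base = dict(channels=(8, 16, 32, 64), depths=(1, 1, 1, 1),
                heads=(1, 2, 4, 8), window=6, mfb_width=16, mlp_ratio=2.0)
    base.update(overrides)
    return ModelConfig(**base)


@pytest.fixture(scope="session")
def tiny_model() -> PMFFNet:
    return PMFFNet(tiny_model_config(), seed=0)


@pytest.fixture(scope="session")
def phantom_pairs_96():
    """Eight preprocessed 96x96 phantom (image, mask) pairs."""
    cfg = PhantomConfig(image_size=(96, 96), seed=11)
    return [preprocess(generate_phantom(cfg, seed=11 + i), side=96)
            for i in range(8)]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
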