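import numpy as np
import pytest

from sefunet.config import ModelConfig
from sefunet.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A compact deterministic phantom shared by data/inference tests."""
    spec = PhantomSpec(shape=(12, 64, 64), seed=11, min_radius=3, max_radius=7)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def tiny_model_config():
    """A model small enough for repeated CPU forward/backward passes."""
    return ModelConfig(dims=(8, 16, 32, 64), depths=(1, 1, 1, 1),
                       decoder_channels=(32, 16, 16, 8), input_size=64,
                       mixer_expansion=2.0, mlp_ratio=2.0, se_reduction=4,
                       dw_kernel_encoder=3, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
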