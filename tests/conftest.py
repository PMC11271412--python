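import numpy as np
import pytest
from hypothesis import settings

from milsurv.model import Model, ModelConfig

settings.register_profile("suite", deadline=None, max_examples=25,
                          derandomize=True)
settings.load_profile("suite")


TINY_CFG = ModelConfig(
    in_dim=5,
    encoder_dims=(6, 4),
    attn_hidden=3,
    embed_dim=4,
    embed_out=3,
    fused_hidden=(8, 6),
    n_bins=4,
    dropout=0.0,
    seed=1,
)


@pytest.fixture
def tiny_model() -> Model:
    return Model(TINY_CFG)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
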