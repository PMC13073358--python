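import numpy as np
import pytest

from ordvit import ModelConfig, SeverityParams, build_model


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    return ModelConfig.tiny()


@pytest.fixture(scope="session")
def micro_config():
    """Smallest usable geometry, for fast forward/backward-pass tests."""
    return ModelConfig(
        image_size=16,
        patch_size=8,
        embed_dim=16,
        depth=1,
        n_heads=2,
        ffn_dim=24,
        sfl_heads=2,
        sfl_hidden=12,
        sfl_out=8,
        dropout=0.0,
    )


@pytest.fixture(scope="session")
def micro_model(micro_config):
    return build_model(micro_config, "full", seed=7)


@pytest.fixture(scope="session")
def default_params():
    return SeverityParams(n_per_class=4, image_size=32, seed=3)
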