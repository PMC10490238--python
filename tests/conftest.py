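import numpy as np
import pytest

from sleepalign import (EncoderConfig, SimConfig, TransformerConfig,
                        generate_recording)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_encoder_config():
    """A narrow encoder for fast unit tests (architecture shape unchanged)."""
    return EncoderConfig(filters=8, reduction_ratio=4, embed_dim=16)


@pytest.fixture
def tiny_transformer_config():
    return TransformerConfig(layers=1, hidden_dim=8, heads=2, embed_dim=16)


@pytest.fixture(scope="session")
def small_recording():
    """A 4-epochs-per-stage synthetic recording shared across tests."""
    config = SimConfig(n_epochs_per_stage=4, seed=99)
    recording, annotations = generate_recording(config)
    return config, recording, annotations
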