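import numpy as np
import pytest

import emoser as E
from emoser.model import ModelConfig, TrainConfig


@pytest.fixture(scope="session")
def synth_spec():
    """The study conditions for the synthetic recovery experiments."""
    return E.SynthSpec(seed=1)


@pytest.fixture(scope="session")
def synth_clips(synth_spec):
    return E.generate_dataset(synth_spec)


@pytest.fixture(scope="session")
def feat_cfg_small():
    """16 Mel bands: collapses to one band after two 4x poolings."""
    return E.FeatureConfig(n_mels=16)


@pytest.fixture(scope="session")
def model_cfg_small():
    """Scaled-down network used for the training experiments in the suite."""
    return ModelConfig(n_classes=3, n_mels=16, n_blocks=2, conv_channels=12,
                       lstm_hidden=24, fc_hidden=32, seed=0)


@pytest.fixture(scope="session")
def train_cfg_fast():
    return TrainConfig(epochs=8, batch_size=8, lr=1e-3, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
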