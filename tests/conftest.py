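import numpy as np
import pytest

from dualdistill import SynthParams, default_model_factory, generate_dataset, smoke_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_params():
    """Small clips that keep convolution tests fast."""
    return SynthParams(n_frames=8, height=24, width=24, blob_radius_range=(4.0, 6.0))


@pytest.fixture
def toy_model():
    return default_model_factory(widths=(2, 4, 6, 8))(seed=7)


@pytest.fixture
def tiny_train_config():
    return smoke_config(epochs=3, frames_per_clip=6, input_size=24, batch_size=4)


@pytest.fixture
def balanced_clips(tiny_params):
    clips, manifest = generate_dataset((4, 4, 4), tiny_params, seed=11)
    return clips, manifest
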