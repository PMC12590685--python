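import numpy as np
import pytest

from maskst.data_model import PreprocessConfig, preprocess
from maskst.masked_gat import ModelConfig
from maskst.simulator import generate_hex_slice, rotate_and_crop


@pytest.fixture(scope="session")
def hex_slice():
    """Small layered hexagonal slice (10×10, 5 layers, 60 genes)."""
    return generate_hex_slice(10, 10, 5, 60, seed=7)


@pytest.fixture(scope="session")
def identical_pair():
    """A reference slice and its exact copy (100% overlap), preprocessed."""
    ref = generate_hex_slice(10, 10, 5, 60, seed=3)
    pair = rotate_and_crop(ref, 0.0)
    slices = preprocess([ref, pair.simulated], PreprocessConfig())
    return slices, pair


@pytest.fixture
def tiny_model_config():
    """Small, fast model configuration for training smoke tests."""
    return ModelConfig(hidden_dim=32, latent_dim=8, projector_hidden=16,
                       epochs_phase1=20, epochs_phase2=10, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
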