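import numpy as np
import pytest

from retinagrade.dwam_attention import DwamConfig
from retinagrade.network import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_model_config():
    """Toy two-stage backbone for CPU-speed tests (64x64 inputs, 8x8 features)."""
    return ModelConfig(seed=0)


@pytest.fixture
def toy_dwam_config():
    """Window sizes that tile an 8x8 final-stage feature map."""
    return DwamConfig(allowed_sizes=(2, 4, 8), variance_grid=8, num_heads=4)


@pytest.fixture(scope="session")
def tiny_dataset():
    """60 synthetic samples over all five grades, shared across tests."""
    from retinagrade.synthetic_fundus import generate_array_dataset
    images, masks, grades = generate_array_dataset(
        (20, 10, 12, 9, 9), image_size=(64, 64), seed=77)
    return images, masks, grades
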