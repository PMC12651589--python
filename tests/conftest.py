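import numpy as np
import pytest

from busseg.model import ModelConfig
from busseg.synthetic import SyntheticSpec, generate_dataset
from busseg.text_embedding import HashingTextEncoder


@pytest.fixture(scope="session")
def tiny_model_config() -> ModelConfig:
    """Reduced-width configuration used for fast CPU tests."""
    return ModelConfig(image_side=96, cg=16, cl=8, reduced_width=16, cond_width=16,
                       local_widths=(8, 16, 24, 32, 32), vit_width=32, embed_dim=64,
                       working_stride=2)


@pytest.fixture(scope="session")
def encoder() -> HashingTextEncoder:
    return HashingTextEncoder(embed_dim=64)


@pytest.fixture(scope="session")
def tiny_samples():
    """A dozen small phantoms shared across tests (read-only)."""
    spec = SyntheticSpec(n_images=12, side=96, lesion_length_range=(14.0, 48.0), seed=7)
    return generate_dataset(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
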