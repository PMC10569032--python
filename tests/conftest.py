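import numpy as np
import pytest

from swunet.network import ModelConfig, SWUNet
from swunet.synthetic_data import PhantomSpec, make_phantom_set


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


#: small but structurally complete configuration used by most network tests
TINY = dict(input_side=32, base_width=4, encoder_depth=2, token_dim=16,
            widening_rate=2, n_heads=2, window_side=4, shift=2)


@pytest.fixture(scope="session")
def tiny_model():
    return SWUNet(ModelConfig(**TINY), seed=0)


@pytest.fixture(scope="session")
def tiny_phantoms():
    """Eight 32x32 binary phantoms for fast training tests."""
    spec = PhantomSpec(side=32, n_lesions=1, lesion_radius_range=(3.0, 6.0), seed=7)
    phantoms = make_phantom_set(8, spec)
    X = np.stack([p.image for p in phantoms])
    y = np.stack([p.mask for p in phantoms])
    return X, y
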