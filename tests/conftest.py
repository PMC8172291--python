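import numpy as np
import pytest

from vesselseg import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def phantom():
    """One 128×128 phantom triple (image, ground truth, FOV), fixed seed."""
    return generate_phantom(PhantomConfig(side=128, seed=42))


@pytest.fixture(scope="session")
def phantom_green(phantom):
    img, gt, fov = phantom
    return img[:, :, 1].astype(np.float64), gt, fov


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
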