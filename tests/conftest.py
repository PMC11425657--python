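import numpy as np
import pytest

from modgan.phantoms import (disc_phantom, make_brain_phantom,
                             toy_brain_tissue_map)
from modgan.projection import radon_forward


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def disc128():
    return disc_phantom(128, 20.0)


@pytest.fixture(scope="session")
def disc128_sino360(disc128):
    angles = np.linspace(0.0, 360.0, 360, endpoint=False)
    return radon_forward(disc128, angles)


@pytest.fixture(scope="session")
def brain_map():
    return toy_brain_tissue_map(96, seed=3)


@pytest.fixture(scope="session")
def brain_phantom(brain_map):
    return make_brain_phantom(brain_map)


def numeric_gradient(tensor, scalar_fn, eps=1e-6):
    """Central finite differences of ``scalar_fn`` w.r.t. ``tensor.data``."""
    grad = np.zeros_like(tensor.data)
    it = np.nditer(tensor.data, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        old = tensor.data[idx]
        tensor.data[idx] = old + eps
        fp = scalar_fn()
        tensor.data[idx] = old - eps
        fm = scalar_fn()
        tensor.data[idx] = old
        grad[idx] = (fp - fm) / (2 * eps)
    return grad
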