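import numpy as np
import pytest

from uldct.phantom import (
    CTImage,
    InsertSpec,
    PhantomSpec,
    render_phantom,
    small_phantom,
)


@pytest.fixture(scope="session")
def small_spec():
    return small_phantom()


@pytest.fixture(scope="session")
def small_clean(small_spec):
    """Noise-free 64x64 render of the scaled-down sensitometry phantom."""
    return render_phantom(small_spec, 64, 1.0)


@pytest.fixture(scope="session")
def uniform_clean():
    """Insert-free uniformity render (128x128) for NPS work."""
    return render_phantom(small_phantom(uniform_module=True), 128, 1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_image(rng, shape=(32, 32), spacing=1.0, lo=-200.0, hi=200.0):
    return CTImage(rng.uniform(lo, hi, shape), (spacing, spacing))
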