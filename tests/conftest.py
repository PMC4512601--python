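import numpy as np
import pytest

import ropvision as rv


@pytest.fixture(scope="session")
def default_phantom():
    """The default study phantom (seed 0), shared across tests."""
    return rv.generate_phantom(rv.PhantomConfig(seed=0))


@pytest.fixture(scope="session")
def default_pipeline(default_phantom):
    """Green plane, filtered plane and VNM map of the default phantom."""
    green = rv.extract_green(default_phantom.image)
    filtered = rv.anisotropic_diffusion(green)
    vnm = rv.vesselness_measure(filtered)
    return {"green": green, "filtered": filtered, "vnm": vnm}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_rgb(rng, shape=(24, 32)):
    return rng.integers(0, 256, size=(*shape, 3), dtype=np.uint8)
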