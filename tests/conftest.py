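import numpy as np
import pytest

from avaplan.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Noiseless default phantom (0.40 cm² orifice) with ground truth."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def noisy_calcified_phantom():
    """Noisy phantom with three off-orifice calcific deposits."""
    spec = PhantomSpec(
        noise_sd=5.0,
        rng_seed=7,
        calcium_blobs=[((95.0, 120.0), 1.5), ((120.0, 95.0), 1.2), ((128.0, 128.0), 1.0)],
    )
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_mask(rng, shape=(32, 32), density=0.35):
    return rng.random(shape) < density
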