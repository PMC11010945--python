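import numpy as np
import pytest

from fetquant.simulate import (
    PhantomSpec,
    SampleTableSpec,
    default_voi_placements,
    generate_phantom,
    generate_reference_panels,
    generate_sample_table,
)
from fetquant.uptake import default_uptake_model


@pytest.fixture(scope="session")
def uptake():
    return default_uptake_model()


@pytest.fixture(scope="session")
def big_sample_table(uptake):
    """10k samples at the default composition, fixed seed."""
    return generate_sample_table(SampleTableSpec(n_samples=10_000, seed=20240301), uptake)


@pytest.fixture(scope="session")
def panels_large(uptake):
    return generate_reference_panels(10_000, uptake, seed=20240302)


@pytest.fixture(scope="session")
def default_phantom(uptake):
    return generate_phantom(PhantomSpec(seed=7), uptake)


@pytest.fixture(scope="session")
def noise_free_phantom(uptake):
    return generate_phantom(PhantomSpec(seed=0, noise_sd=0.0), uptake)


@pytest.fixture(scope="session")
def placements():
    return default_voi_placements()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
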