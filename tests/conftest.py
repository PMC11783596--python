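import numpy as np
import pytest

from sgdefaug.core import ImageGeometry, ScalarVolume, structures_to_labelmap
from sgdefaug.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom():
    """One deterministic full-size phantom shared across tests."""
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def clean_phantom():
    """Same phantom without bias field or noise (organ contrast intact)."""
    return generate_phantom(
        PhantomSpec(seed=1, bias_field_amplitude=0.0, rician_sigma=0.0)
    )


@pytest.fixture(scope="session")
def phantom_labelmap(phantom):
    _, ss = phantom
    return structures_to_labelmap(ss)


@pytest.fixture
def small_geom():
    return ImageGeometry((16, 16, 16), (2.0, 2.0, 2.0), (-15.0, -15.0, -15.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_volume(geom: ImageGeometry, seed: int = 0) -> ScalarVolume:
    g = np.random.default_rng(seed)
    return ScalarVolume(geom, g.normal(size=geom.size))
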