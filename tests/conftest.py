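import numpy as np
import pytest

from hspdyn import (DomainDefinition, make_ideal_helix,
                    make_two_domain_complex)


@pytest.fixture(scope="session")
def helix30():
    return make_ideal_helix(30)


@pytest.fixture(scope="session")
def helix_ca_domain():
    return DomainDefinition("helix-ca", "A", ((1, 30),), frozenset({"CA"}))


@pytest.fixture(scope="session")
def complex_close():
    """Two 12-residue helical bodies close enough to form an interface."""
    return make_two_domain_complex(12, 12, 9.0, seed=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
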