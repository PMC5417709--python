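import numpy as np
import pytest

from wraplab import synthetic as syn


@pytest.fixture(scope="session")
def helix12():
    """Ideal 12-residue poly-ALA helix with its ground-truth bond list."""
    return syn.build_ideal_helix(12)


@pytest.fixture(scope="session")
def dimer_spec():
    return syn.sod1_like_dimer_spec(seed=11)


@pytest.fixture(scope="session")
def dimer_traj(dimer_spec):
    return syn.sample_gnm_trajectory(dimer_spec, 400)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng):
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
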