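import numpy as np
import pytest

from chromofibre.chromatosome import generate_ideal_chromatosome
from chromofibre.fixtures import default_mini_fibre_params, make_fixture, FixtureSpec


@pytest.fixture(scope="session")
def template():
    """Canonical synthetic chromatosome template."""
    return generate_ideal_chromatosome()


@pytest.fixture(scope="session")
def mini_fibre_2start(template):
    from chromofibre.fibre import build_fibre

    return build_fibre(template, default_mini_fibre_params("2-start", n_nuc=8))


@pytest.fixture(scope="session")
def mini_fibre_1start(template):
    from chromofibre.fibre import build_fibre

    return build_fibre(template, default_mini_fibre_params("1-start", n_nuc=12))


def random_rotation(rng):
    """Uniform-ish random proper rotation matrix."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@pytest.fixture
def rand_curve():
    def _make(n=60, seed=0, scale=10.0):
        return make_fixture(FixtureSpec("random_smooth_curve", {"n": n, "scale": scale}, seed=seed))

    return _make
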