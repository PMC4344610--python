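import numpy as np
import pytest

from glyconf.geometry import default_geometry, default_linkage_spec


def angdiff(a, b):
    """Absolute angular difference in degrees, wrap-aware."""
    return np.abs(((np.asarray(a) - np.asarray(b) + 180.0) % 360.0) - 180.0)


@pytest.fixture(scope="session")
def spec():
    return default_linkage_spec()


@pytest.fixture(scope="session")
def geom(spec):
    return default_geometry(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20150212)


def random_rigid_motion(rng):
    """A uniformly random proper rotation matrix and a translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    return rot, rng.normal(size=3) * 5.0
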