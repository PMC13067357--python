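import numpy as np
import pytest

from pcammd.materials import build_default_library


@pytest.fixture(scope="session")
def lib():
    return build_default_library()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_triangle(rng, scale=1000.0, min_area=1e4):
    """A random well-conditioned triangle in HU-like units.

    The area floor rejects near-degenerate slivers, for which no
    coordinate computation (area-based or linear solve) is well posed;
    the library enforces the same kind of floor on its domains.
    """
    while True:
        tri = rng.uniform(-scale, scale, size=(3, 2))
        area = 0.5 * abs(
            (tri[1, 0] - tri[0, 0]) * (tri[2, 1] - tri[0, 1])
            - (tri[2, 0] - tri[0, 0]) * (tri[1, 1] - tri[0, 1])
        )
        if area > min_area:
            return tri
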