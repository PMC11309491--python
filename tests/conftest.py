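import numpy as np
import pytest

from cellalign.geometry import EllipseSpec, intersect
from cellalign.shape_dynamics import axes_from_r


def random_ellipse(rng, box=20.0, r_range=(1.0, 4.0), centre=None):
    r = rng.uniform(*r_range)
    a, b = axes_from_r(r)
    X = rng.uniform(0, box, 2) if centre is None else np.asarray(centre, float)
    return EllipseSpec(X, rng.uniform(0, 2 * np.pi), a, b)


def random_overlapping_pair(rng, box=20.0, max_tries=50):
    """A pair of unit-area ellipses with a non-degenerate overlap contact."""
    for _ in range(max_tries):
        e1 = random_ellipse(rng, box)
        e2 = random_ellipse(rng, box,
                            centre=(e1.centre + rng.uniform(-1.5, 1.5, 2)) % box)
        ct = intersect(e1, e2, box)
        if ct is not None and ct.degenerate_flag != "containment":
            return e1, e2, ct
    raise RuntimeError("could not draw an overlapping pair")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
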