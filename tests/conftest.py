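import numpy as np
import pytest

from nucleograde.features import CentroidSet


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_section(rng):
    """A 200-point homogeneous section on the default 750x750 extent."""
    pts = rng.uniform(0, 750, size=(200, 2))
    return CentroidSet("P0", "P0_S0", pts, (750.0, 750.0))


def make_section(points, extent=(750.0, 750.0)):
    return CentroidSet("P0", "P0_S0", np.asarray(points, float), extent)
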