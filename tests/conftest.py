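import numpy as np
import pytest

from ramp import synthetic as syn


@pytest.fixture(scope="session")
def circle_geometry():
    """A 201×201 circular cell, radius 100 px, nucleus radius 20 px."""
    return syn.make_geometry("circle", cell_radius=100.0, nucleus_radius=20.0, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
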