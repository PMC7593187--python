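import numpy as np
import pytest

from refugia.synthio import WorldSpec, make_world


@pytest.fixture(scope="session")
def world():
    """The default synthetic study system (generated once per session)."""
    return make_world(WorldSpec())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
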