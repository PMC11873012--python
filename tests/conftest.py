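import numpy as np
import pytest

from ratvision.geometry import ViewingGeometry
from ratvision.stimuli import make_canonical_objects


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def geom():
    """Standard rig geometry: 224 px display spanning ~96 degrees."""
    return ViewingGeometry()


@pytest.fixture(scope="session")
def geom64():
    """Reduced-resolution geometry for fast end-to-end runs."""
    return ViewingGeometry(res_w=64, res_h=64, ppd=64 / 96.0)


@pytest.fixture(scope="session")
def objects():
    return make_canonical_objects()
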