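import numpy as np
import pytest

from endotrack import AcquisitionGeometry


@pytest.fixture(scope="session")
def geom():
    """Standard high-speed acquisition: 28 fps, 11.72 px/µm."""
    return AcquisitionGeometry()


@pytest.fixture(scope="session")
def wide_geom():
    """Larger field for populations with long translocations."""
    return AcquisitionGeometry(field_size=(80.0, 80.0), cell_centre=(40.0, 40.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
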