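import pytest

from tebmodel.fixtures import reconstructed_region_params, reference_config
from tebmodel.geometry import reference_geometry


@pytest.fixture(scope="session")
def geometry_fixture():
    return reference_geometry()


@pytest.fixture(scope="session")
def region_params():
    return reconstructed_region_params()


@pytest.fixture
def config():
    return reference_config()
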