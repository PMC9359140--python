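from importlib import resources

import pytest

from qtransport import nuclide_data as nd
from qtransport.spectrum_engine import analytic_curveset
from qtransport.validation import load_reference_values


@pytest.fixture(scope="session")
def curveset():
    return analytic_curveset()


@pytest.fixture(scope="session")
def reference():
    return load_reference_values()


def _packaged(name: str):
    return str(resources.files("qtransport.data") / name)


@pytest.fixture(scope="session")
def control_library():
    return nd.read_library(_packaged("control_group.yaml"))


@pytest.fixture(scope="session")
def medical_library():
    return nd.read_library(_packaged("medical_radionuclides.yaml"))


@pytest.fixture()
def packaged_path():
    return _packaged
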