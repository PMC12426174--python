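import pytest

from catelute.model_core import (
    default_protocol,
    reference_parameters,
    standard_geometry,
)
from catelute.radial_solver import NumericsConfig


@pytest.fixture(scope="session")
def geometry_14fr():
    return standard_geometry("14Fr")


@pytest.fixture(scope="session")
def geometry_20fr():
    return standard_geometry("20Fr")


@pytest.fixture(scope="session")
def control_params():
    return reference_parameters("control")


@pytest.fixture(scope="session")
def lbl_params():
    return reference_parameters("LbL")


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def coarse_numerics():
    """Cheap numerics for structural tests where accuracy is not the point."""
    return NumericsConfig(n_nodes=51, dt_load=0.05, dt_rest=0.25, dt_delivery=0.5, store_wall="boundaries")
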