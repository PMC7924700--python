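import pytest

from tcob.engine import ConstraintStore, TimeGrid
from tcob.neurons import HHParams


@pytest.fixture
def hh_params() -> HHParams:
    """Classic squid-axon set shifted to rest at -70 mV."""
    return HHParams()


@pytest.fixture
def tiny_store() -> ConstraintStore:
    """A five-tick store with unit dt for structural engine tests."""
    return ConstraintStore(TimeGrid(t_end=5, dt=1.0))
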