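import pytest
from hypothesis import settings

from microdev.models import TwoPopParams, VolumeParams
from microdev.topology import RegionTopology

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def single_layer_topo():
    return RegionTopology("region", ("L",))


@pytest.fixture
def const_volume():
    """Frozen unit-ish volume (g=0) so densities and counts coincide up to V."""
    return {"L": VolumeParams(2.0, 2.0, 0.0)}


@pytest.fixture
def chain_topo():
    return RegionTopology("chain", ("a", "b", "c"), (("a", "b"), ("b", "c")))


@pytest.fixture
def decoupled_two_pop(const_volume):
    """Closed-form case: A(t) = A0 exp((a1-a2-c) t), B fed only by A."""
    return TwoPopParams(
        a1_int_A=0.5, a2_int_AB=0.2, c_A=0.1,
        A0={"L": 1.0}, B0={}, volume=const_volume,
    )
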