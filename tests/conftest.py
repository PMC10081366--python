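import pytest

import serovolt as sv
from serovolt import mm


@pytest.fixture(scope="session")
def control_params() -> sv.MMParams:
    """Control-state dual-uptake parameterisation."""
    return sv.CONTROL_PARAMS


@pytest.fixture(scope="session")
def protocol() -> sv.StimulationProtocol:
    """The in vivo 60 Hz, 2 s stimulation train."""
    return sv.StimulationProtocol()


@pytest.fixture(scope="session")
def control_trace(control_params, protocol):
    """Noiseless forward simulation of the control state."""
    return mm.simulate(control_params, protocol)
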