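import numpy as np
import pytest

from dgephys import model, simulate


@pytest.fixture
def reference_ipi_grid():
    """Paired-pulse interpulse intervals of the reference protocol (ms)."""
    return np.asarray(simulate.DEFAULT_IPIS_MS)


@pytest.fixture
def lif_no_adaptation():
    """LIF cell with adaptation and block disabled: closed-form rheobase
    g_L * (V_th - E_L) = 150 pA."""
    return simulate.NeuronParams(g_L_nS=10.0, E_L_mV=-80.0, V_th_mV=-65.0,
                                 b_pA=0.0, block_enabled=False)


@pytest.fixture
def step_protocol_0_300():
    return model.StepProtocol(0.0, 300.0, 10.0)
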