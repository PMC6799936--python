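import numpy as np
import pytest

from spikefp.meanfield import SynapticConfig
from spikefp.models import eif_neuron, lif_neuron, vif_neuron


@pytest.fixture(scope="session")
def lif():
    return lif_neuron(tau_m=20.0, C_m=500.0, v_thr=20.0, v_res=0.0)


@pytest.fixture(scope="session")
def vif():
    return vif_neuron()


@pytest.fixture(scope="session")
def eif():
    return eif_neuron()


@pytest.fixture(scope="session")
def vif_dd_config():
    """Drift-dominated excitatory VIF network (10-Hz design)."""
    return SynapticConfig(N=2000, C=100, J=0.0075, J_ext=0.0114, C_ext=300,
                          nu_ext=10.0, I_DC=-0.032, delta_min=10.0)


@pytest.fixture(scope="session")
def vif_nd_config():
    """Noise-dominated excitatory VIF network (10-Hz design)."""
    return SynapticConfig(N=2000, C=100, J=0.014, J_ext=0.0726, C_ext=300,
                          nu_ext=10.0, I_DC=-0.242, delta_min=10.0)


@pytest.fixture(scope="session")
def lif_dd_config():
    """Drift-dominated excitatory LIF network (40-Hz design)."""
    return SynapticConfig(N=2000, C=100, J=0.140, J_ext=0.272, C_ext=300,
                          nu_ext=40.0, I_DC=-1230.0, delta_min=3.0)


@pytest.fixture(scope="session")
def lif_nd_config():
    """Noise-dominated excitatory LIF network (40-Hz design)."""
    return SynapticConfig(N=2000, C=100, J=0.213, J_ext=1.518, C_ext=300,
                          nu_ext=40.0, I_DC=-9160.0, delta_min=3.0)
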