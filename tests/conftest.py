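import numpy as np
import pytest

from eadkit.model import control_parameters, default_initial_state, apply_scaling


#: the four representative scaled-parameter points used throughout
REPRESENTATIVE_ALPHA = {
    "typeI": dict(k_max=2, J_Caslmyo=2.64, I_NCX_bar=1, G_Ks=1.16, P_Ca=5.4),
    "typeII": dict(k_max=7, J_Caslmyo=3.6, I_NCX_bar=2.2, G_Ks=0.56, P_Ca=2.8),
    "typeIII": dict(k_max=2, J_Caslmyo=2.64, I_NCX_bar=1, G_Ks=1.6, P_Ca=8.2),
    "typeIV": dict(k_max=7, J_Caslmyo=1, I_NCX_bar=1.2, G_Ks=1, P_Ca=1),
}


@pytest.fixture(scope="session")
def rest_state():
    return default_initial_state()


@pytest.fixture(scope="session")
def control():
    return control_parameters()


def scaled(alpha):
    return apply_scaling(control_parameters(), alpha)
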