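import numpy as np
import pytest

from multicup.dgim_transfer import DGIMConfig
from multicup.solubility import PHSolubilityFit
from multicup.synthetic_data import (
    LuminalKineticsParams,
    PKDispositionParams,
    default_kinetics,
    default_scenario,
)


@pytest.fixture(scope="session")
def dgim_cfg():
    return DGIMConfig()


@pytest.fixture(scope="session")
def control_scenario():
    return default_scenario("control")


@pytest.fixture(scope="session")
def control_kinetics():
    return default_kinetics("control")


@pytest.fixture(scope="session")
def minute_grid():
    return np.arange(0.0, 180.0 + 1e-9, 1.0)


@pytest.fixture(scope="session")
def pk_params():
    return PKDispositionParams()


@pytest.fixture(scope="session")
def solubility_fit():
    return PHSolubilityFit(C_U=18.0, pKa=6.322)
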