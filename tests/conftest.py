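import numpy as np
import pytest

import ccrelax as cx


@pytest.fixture(scope="session")
def methanol():
    """Bundled calibrated 13CH3 system (rotating-top motional model)."""
    return cx.load_spin_system("ch3_methanol")


@pytest.fixture(scope="session")
def eg():
    """Bundled calibrated 13CH2 system (rigid isotropic tumbling)."""
    return cx.load_spin_system("ch2_eg")


@pytest.fixture(scope="session")
def methanol_R(methanol):
    return cx.assemble_relaxation(methanol, 11.7)


@pytest.fixture(scope="session")
def eg_R(eg):
    return cx.assemble_relaxation(eg, 11.7)


@pytest.fixture(scope="session")
def ch_pair():
    """Isolated heteronuclear 13C-1H pair without J coupling (Solomon regime)."""
    def make(tau_c, j_hz=0.0):
        j = np.array([[0.0, j_hz], [j_hz, 0.0]])
        return cx.SpinSystem([("C", "13C"), ("H", "1H")], [0.0, 0.0], j,
                             np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.09]]),
                             tau_c=tau_c)
    return make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240608)
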