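import numpy as np
import pytest

from hemepr import ExperimentCW, GTensor, SpinSystem, simulate_cw


@pytest.fixture(scope="session")
def resting_system() -> SpinSystem:
    """Resting-state ferric enzyme: rhombic g with published strain/linewidth."""
    return SpinSystem(
        g=GTensor(2.44, 2.25, 1.92, 0.005, 0.002, 0.002, label="resting"),
        gstrain=(0.040, 0.0080, 0.010),
        lw_mT=2.0,
    )


@pytest.fixture(scope="session")
def xband_exp() -> ExperimentCW:
    return ExperimentCW(mw_freq_GHz=9.68, field_min_mT=200.0, field_max_mT=420.0,
                        n_points=2048, harmonic="first_derivative")


@pytest.fixture(scope="session")
def xband_abs_exp(xband_exp) -> ExperimentCW:
    return ExperimentCW(mw_freq_GHz=9.68, field_min_mT=200.0, field_max_mT=420.0,
                        n_points=2048, harmonic="absorption")


@pytest.fixture(scope="session")
def resting_deriv(resting_system, xband_exp):
    return simulate_cw(resting_system, xband_exp, n_orientations=2000)


@pytest.fixture(scope="session")
def resting_abs(resting_system, xband_abs_exp):
    return simulate_cw(resting_system, xband_abs_exp, n_orientations=2000)
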