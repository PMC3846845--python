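import numpy as np
import pytest

import ittm


@pytest.fixture(scope="session")
def me180_params():
    """ME180-like transport truth: alpha = 3 exactly, MVP = 6.71 mmHg."""
    return ittm.TransportParameters(
        cfc=2.0e-7 * (3.0 / 0.41) ** 2, k_int=2.0e-7, p_v=6.71, radius=0.41
    )


@pytest.fixture(scope="session")
def me180_plasma():
    return ittm.PlasmaDecayModel(c0=11.2, t_half=38.0)


@pytest.fixture(scope="session")
def me180_times():
    return np.array([1.0 / 12.0, 1.0, 8.0, 24.0, 48.0, 72.0, 96.0, 120.0, 144.0])


@pytest.fixture(scope="session")
def me180_noiseless_curve(me180_params, me180_plasma, me180_times):
    """Noiseless interstitial accumulation curve at the fit's own grid."""
    fld = ittm.simulate_radial_transport(
        me180_params, me180_plasma, times_hr=me180_times, n_nodes=101
    )
    return ittm.AccumulationCurve(
        me180_times, ittm.volume_average(fld).conc[1:], "interstitial"
    )
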