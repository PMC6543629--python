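import numpy as np
import pytest

from pairq import FluorWindow, SimParams, default_sets, simulate_plate


@pytest.fixture(scope="session")
def window():
    return FluorWindow(20.0, 180.0)


@pytest.fixture(scope="session")
def noiseless_plate():
    """16 replicate two-fold six-sets, no noise, no saturation: every reading
    equals the classical exponential model exactly."""
    params = SimParams(e_true=0.8, noise_sd=0.0, plateau=np.inf, seed=1)
    return simulate_plate(params), default_sets(params), params


@pytest.fixture(scope="session")
def noisy_plate():
    """Default study conditions: E=0.8, 16 sets x 6 steps x 33 cycles,
    noise sd 3 RFU, plateau 2000 RFU."""
    params = SimParams(seed=1)
    return simulate_plate(params), default_sets(params), params
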