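import numpy as np
import pytest
from hypothesis import settings

import ufdexsy as u

settings.register_profile("default", derandomize=True, max_examples=25)
settings.load_profile("default")


@pytest.fixture(scope="session")
def block():
    """Reference spatial/diffusion encoding block (15 ms / 144 kHz / 508 mT/m)."""
    return u.default_encoding_block()


@pytest.fixture(scope="session")
def readout():
    """Reference CPMG read-out (32 echoes, 8 ms echo time, 268 mT/m read)."""
    return u.default_cpmg_readout()


@pytest.fixture(scope="session")
def conv_block():
    """Reference conventional block (16 steps, 26.7-508 mT/m, tau_M = 1 s)."""
    return u.default_conventional_block()


@pytest.fixture(scope="session")
def vesicle_system():
    """Two-site water/vesicle system: D 1.9e-9 / 6.0e-11, x_F 0.76, k 28."""
    return u.decanoate_water_system()


@pytest.fixture(scope="session")
def alt_system():
    """Ground truth of the full-model recovery fixture (k 27.9, x_F 0.70)."""
    return u.TwoSiteSystem.mass_conserving(
        d_free=1.49e-9, d_enc=5.3e-11, x_free=0.70, k_total=19.5 + 8.4,
        r1_free=1.0 / 9.96, r1_enc=1.0 / 9.98,
    )


@pytest.fixture(scope="session")
def no_exchange_system():
    """Two diffusion pools with exchange switched off."""
    return u.TwoSiteSystem(d_free=1.9e-9, d_enc=6.0e-11, x_free=0.76,
                           k_ef=0.0, k_fe=0.0)
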