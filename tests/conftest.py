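import numpy as np
import pytest

import fexbci


@pytest.fixture(scope="session")
def small_epochs():
    """40 strongly separable epochs at a reduced 125 Hz rate (8 x 500)."""
    return fexbci.generate_epochs(10, fexbci.default_signatures(gain=4.0),
                                  fs=125.0, seed=11)


@pytest.fixture(scope="session")
def clean_1khz_epoch():
    """One clean epoch set at the native 1 kHz rate (8 x 4000)."""
    return fexbci.generate_epochs(1, fs=1000.0, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
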