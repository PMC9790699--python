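import numpy as np
import pytest

import cdti


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default-protocol phantom with noise and motion disabled."""
    cfg = cdti.PhantomConfig(grid_size=(64, 64), snr=np.inf, seed=11)
    truth, dataset = cdti.simulate(cfg)
    return cfg, truth, dataset


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-protocol phantom at the study SNR."""
    cfg = cdti.PhantomConfig(grid_size=(64, 64), snr=25.0, seed=23)
    truth, dataset = cdti.simulate(cfg)
    return cfg, truth, dataset


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_phantom):
    cfg, truth, dataset = noiseless_phantom
    return cfg, truth, cdti.lls_fit(dataset)
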