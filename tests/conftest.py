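import numpy as np
import pytest

from sslforward import Medium, load_config


@pytest.fixture(scope="session")
def config():
    return load_config()


@pytest.fixture(scope="session")
def medium():
    return Medium()


@pytest.fixture(scope="session")
def band_grid(config):
    """Full 2-kHz frequency grid over the echosounder bands."""
    return config.frequency_grid()


@pytest.fixture(scope="session")
def coarse_grid():
    """Reduced grid for expensive closed-loop runs."""
    return np.concatenate([[18.0, 38.0], np.arange(47.0, 90.1, 6.0),
                           np.arange(95.0, 160.1, 6.0),
                           np.arange(180.0, 240.1, 6.0),
                           np.arange(280.0, 420.1, 10.0)])
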