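import numpy as np
import pytest

from courtsig.basis import RaisedCosineBasis
from courtsig.synth import SynthConfig, generate_tracks


@pytest.fixture(scope="session")
def basis50():
    """Default 4-bump basis on a 1 s window at 50 Hz."""
    return RaisedCosineBasis(n_basis=4, window_s=1.0, rate_hz=50.0)


@pytest.fixture(scope="session")
def short_tracks():
    """A 30 s synthetic recording shared across tests."""
    return generate_tracks(SynthConfig(duration_s=30.0, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
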