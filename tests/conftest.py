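import numpy as np
import pytest

from polyphase import ModelParams
from polyphase.sampler import _random_coil


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def params_stiff():
    return ModelParams(kappa=2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_valid_conformation(n, rng, params):
    """A random coil whose bonds all sit safely inside the FENE interval."""
    conf = _random_coil(n, rng)
    # small random kicks that keep bonds valid
    for _ in range(3):
        trial = conf.positions + rng.normal(0, 0.05, conf.positions.shape)
        b = np.linalg.norm(np.diff(trial, axis=0), axis=1)
        if np.all(np.abs(b - params.r0) < 0.9 * params.r_fene):
            conf.positions = trial
    return conf
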