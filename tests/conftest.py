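import logging

import numpy as np
import pytest

from pars_stain import signals, synth

logging.getLogger("pars_stain").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_raster(values, dt=1.0, schedule=((signals.EX266, 0.0),)):
    """Single-pixel raster from a 1-D sample list."""
    arr = np.asarray(values, dtype=float).reshape(1, 1, -1)
    return signals.TDSignalRaster(arr, dt, schedule)


@pytest.fixture(scope="session")
def skin_phantom():
    """Default noisy skin-like phantom (small, shared across tests)."""
    return synth.generate_phantom(synth.skin_phantom_spec(96, 96, seed=3))


@pytest.fixture(scope="session")
def noiseless_skin_phantom():
    return synth.generate_phantom(
        synth.skin_phantom_spec(96, 96, seed=3, noise_sd=0.0)
    )
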