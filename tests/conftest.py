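import numpy as np
import pytest

from tempopet.grid_io import FrameSchedule, VoiMask
from tempopet import phantom


@pytest.fixture(scope="session")
def schedule_16x150() -> FrameSchedule:
    return FrameSchedule.uniform(600.0, 16, 150.0)


@pytest.fixture(scope="session")
def default_plasma(schedule_16x150):
    return phantom.simulate_plasma_input(phantom.DEFAULT_PLASMA_PARAMS,
                                         schedule_16x150)


@pytest.fixture(scope="session")
def noiseless_phantom():
    return phantom.generate_phantom(seed=11, noise_sd=0.0)


@pytest.fixture(scope="session")
def noisy_phantom():
    return phantom.generate_phantom(seed=11, noise_sd=0.05)


def random_level_volume(rng, shape=(6, 6, 6), ng=4, p_mask=0.7) -> np.ndarray:
    """Random discretised VOI: levels 1..ng inside a random mask, 0 outside."""
    vol = rng.integers(1, ng + 1, size=shape)
    mask = rng.random(shape) < p_mask
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    return np.where(mask, vol, 0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
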