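import numpy as np
import pytest

from trxss import synthetic
from trxss.datamodel import QGrid
from trxss.timing import TriggerScheme


@pytest.fixture(scope="session")
def standard_scheme() -> TriggerScheme:
    """The standard acquisition protocol: 500 Hz, 4 s steps, 1 s laser delay."""
    return TriggerScheme(train_duration=3.0)


@pytest.fixture(scope="session")
def small_scheme() -> TriggerScheme:
    """Short steps for fast tests: 100 frames at 500 Hz, pulse at 0.05 s."""
    return TriggerScheme(frame_rate=500.0, readout_dead_time=100e-6,
                         step_duration=0.2, dt1=0.05, tw1=2e-3,
                         train_duration=0.1)


@pytest.fixture(scope="session")
def coarse_grid() -> QGrid:
    return synthetic.default_grid(saxs_step=0.05, waxs_step=0.05)


@pytest.fixture(scope="session")
def default_grid() -> QGrid:
    return synthetic.default_grid()


@pytest.fixture()
def noise_free() -> synthetic.NoiseConfig:
    return synthetic.NoiseConfig(seed=1, poisson=False)


@pytest.fixture()
def clean_noise_free() -> synthetic.NoiseConfig:
    """Noise-free and free of drift/damage systematics."""
    return synthetic.NoiseConfig(seed=1, poisson=False, drift_amplitude=0.0,
                                 damage_slope=0.0)


def make_noise(seed: int, **kw) -> synthetic.NoiseConfig:
    return synthetic.NoiseConfig(seed=seed, **kw)
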