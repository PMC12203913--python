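import numpy as np
import pytest

from curtainkit.config import EquilibriumParams, SimConfig, Trajectory


@pytest.fixture
def default_cfg() -> SimConfig:
    return SimConfig(rng_seed=0)


@pytest.fixture
def noise_free_cfg() -> SimConfig:
    """Long noise-free sliding configuration for closed-form checks."""
    return SimConfig(
        rng_seed=3,
        n_frames=10_001,
        localization_sigma_kbp=0.0,
        observation_window_s=1e9,
    )


@pytest.fixture
def stationary_track() -> Trajectory:
    return Trajectory("stat", np.arange(20) * 0.1, np.full(20, 10.0))


@pytest.fixture
def default_params() -> EquilibriumParams:
    return EquilibriumParams()
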