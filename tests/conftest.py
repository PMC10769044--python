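import numpy as np
import pytest

from respmotion import (
    PipelineConfig,
    TrainConfig,
    VentilatorSpec,
    generate_trajectory,
)


@pytest.fixture(scope="session")
def default_spec():
    return VentilatorSpec()


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free, single-axis ventilator spec for exact geometric checks."""
    return VentilatorSpec(noise_sd=0.0, secondary_amplitude=0.0, quat_jitter=0.0)


@pytest.fixture(scope="session")
def default_trajectory(default_spec):
    """The standard 30 s / 30 Hz benchmark recording (900 frames, seed 7)."""
    return generate_trajectory(default_spec, duration_s=30.0, rate_hz=30.0, seed=7)


@pytest.fixture(scope="session")
def short_trajectory(default_spec):
    """A 12 s recording: large enough to split with L=50, h=10, fast to fit."""
    return generate_trajectory(default_spec, duration_s=12.0, rate_hz=30.0, seed=3)


@pytest.fixture
def quick_train_cfg():
    return TrainConfig(epochs=2, lr_switch_epoch=1, seed=0)


@pytest.fixture
def quick_pipeline_cfg(quick_train_cfg):
    return PipelineConfig(hidden=8, latent=4, train_cfg=quick_train_cfg)
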