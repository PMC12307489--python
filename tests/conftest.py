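import numpy as np
import pytest

from hafusenet.models import DisnetConfig, FusionConfig, LsnetConfig, ModelConfig
from hafusenet.synth import SynthConfig, _default_profiles


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def tiny_model_config(n_times: int = 64, n_channels: int = 6) -> ModelConfig:
    """Smallest config that exercises every architectural element."""
    return ModelConfig(
        disnet=DisnetConfig(
            n_channels=n_channels,
            n_times=n_times,
            stem_depth=3,
            stem_kernel=5,
            bottleneck_expansion=2,
            bottleneck_kernel=5,
            branch_kernels=(3, 5),
            branch_depth=2,
            pool_size=16,
            dropout=0.0,
        ),
        lsnet=LsnetConfig(n_layers=1, hidden=8, time_pool=4),
        fusion=FusionConfig(target_depth=3, kernel=3),
    )


def tiny_synth_config(
    n_trials_per_class: int = 3, attenuation: float = 0.3, seed: int = 5
) -> SynthConfig:
    """Short 4-channel sessions for fast io/protocol tests."""
    profiles = [
        {0: (10.0, 2.0, attenuation)},
        {1: (10.0, 2.0, attenuation)},
        {2: (10.0, 2.0, attenuation)},
        {3: (10.0, 2.0, attenuation)},
    ]
    return SynthConfig(
        n_subjects=2,
        n_trials_per_class=n_trials_per_class,
        sampling_rate=32.0,
        n_channels=4,
        class_profiles=profiles,
        noise_sd=0.3,
        trial_period=5.0,
        seed=seed,
    )


@pytest.fixture
def tiny_cfg():
    return tiny_model_config()


@pytest.fixture
def default_profiles():
    return _default_profiles()
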