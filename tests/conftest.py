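import numpy as np
import pytest

from tasteeg.model import BranchSpec, ModelConfig
from tasteeg.synth import SynthConfig, generate_dataset

# Small-but-learnable setup used by training tests: 128 Hz, 4-s trials,
# 128-sample windows.  Class bands all sit inside [8, 40] Hz so the same
# bandpass defaults apply.
TINY_PROFILES = {
    "water": ((10.0, 2.0, 1.0),),
    "sucrose": ((16.0, 2.0, 1.0),),
    "aspartame": ((24.0, 2.0, 1.0),),
    "sucralose": ((32.0, 2.0, 1.0),),
}


def tiny_synth_config(effect_size: float = 6.0, seed: int = 0, n_subjects: int = 6,
                      n_sessions: int = 1) -> SynthConfig:
    return SynthConfig(
        n_subjects=n_subjects,
        n_sessions_per_subject=n_sessions,
        fs=128.0,
        duration_s=4.0,
        class_profiles=TINY_PROFILES,
        effect_size=effect_size,
        seed=seed,
    )


def tiny_model_config(window_len: int = 128, n_channels: int = 2) -> ModelConfig:
    return ModelConfig(
        branches=(
            BranchSpec(n_filters=8, kernel_len=5, pool_len=4),
            BranchSpec(n_filters=8, kernel_len=11, pool_len=4),
            BranchSpec(n_filters=8, kernel_len=21, pool_len=4),
        ),
        input_shape=(window_len, n_channels),
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """6 subjects x 1 session x 4 classes = 24 highly separable recordings."""
    return generate_dataset(tiny_synth_config(effect_size=6.0, seed=11))
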