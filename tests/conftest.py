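import numpy as np
import pytest

from eegmixer import (
    ConvMixerECA,
    ModelConfig,
    SyntheticSpec,
    preprocess_recordings,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Ten subjects per class, 20-s recordings: enough epochs for splits."""
    spec = SyntheticSpec(n_subjects_per_class=10, recording_seconds=20.0, seed=11)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_epochs(small_cohort):
    return preprocess_recordings(small_cohort)


@pytest.fixture
def tiny_model():
    """A model small enough for exhaustive checks."""
    cfg = ModelConfig(in_channels=3, hidden_dim=8, depth=2, patch_size=4,
                      dw_kernel=3, n_classes=2)
    return ConvMixerECA(cfg, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
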