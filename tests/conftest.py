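import numpy as np
import pytest

from onsnn import EEGSegment, NetworkConfig, SynthConfig, generate_stream


@pytest.fixture
def segment():
    """A small deterministic 2-channel segment."""
    rng = np.random.default_rng(42)
    return EEGSegment(values=rng.standard_normal((2, 64)),
                      channel_names=("a", "b"))


@pytest.fixture
def small_config():
    """Default hyperparameters with a hidden layer sized for fast tests."""
    return NetworkConfig(n_hidden=20, seed=7)


@pytest.fixture
def small_stream():
    """An 18-sample synthetic stream (6 per class, short segments)."""
    cfg = SynthConfig(n_samples=18, duration=1.0, seed=3)
    return generate_stream(cfg)
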