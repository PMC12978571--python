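import numpy as np
import pytest

from loomdyn import SimConfig


@pytest.fixture
def tiny_config():
    """Two subjects per arm, one repetition per factorial cell."""
    return SimConfig(n_subjects_per_arm=2, repetitions=1, seed=123)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
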