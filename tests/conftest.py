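import numpy as np
import pytest

from uncagekit import SceneParams
from uncagekit.photochemistry import PhotoreactionParams


@pytest.fixture
def ref_reaction():
    """Reference rate set used throughout: k_u=1, k_b=0.1, k_a=0.05, D=1."""
    return PhotoreactionParams(k_u=1.0, k_b=0.1, k_a=0.05, dose=1.0)


@pytest.fixture
def noisefree_scene():
    return SceneParams(shot_noise=False, read_noise_sigma=0.0, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
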