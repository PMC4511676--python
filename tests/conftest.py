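import numpy as np
import pytest

from salbias import SceneSpec, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_scene():
    """One easy scene: big contrasting ellipse, no distractors, no noise."""
    spec = SceneSpec(height=64, width=96, noise_sigma=0.0, n_distractors=0,
                     n_background_bands=1, area_fraction=(0.1, 0.2))
    images, masks, manifest = make_dataset(1, spec, seed=7)
    return images[0], masks[0], manifest.iloc[0]


@pytest.fixture(scope="session")
def scene_batch():
    """A dozen default-condition scenes shared across tests."""
    images, masks, manifest = make_dataset(12, SceneSpec(), seed=11)
    return images, masks, manifest
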