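import numpy as np
import pytest

from penyek import imgen


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_patch_dataset():
    """40 RGB patches (20/class), distortion 0.5, 21 px — shared by the
    classifier and evaluation unit tests."""
    splits = imgen.generate_dataset(
        20, 20, (0.6, 0.2, 0.2), patch_size=21,
        cfg=imgen.SceneConfig(distortion=0.5), seed=7,
    )
    return splits["train"] + splits["val"] + splits["test"]


@pytest.fixture(scope="session")
def demo_scene():
    cfg = imgen.SceneConfig(256, 256, 3, 3, distortion=0.3, seed=5)
    scene, gt = imgen.generate_scene(cfg, image_id="demo")
    return cfg, scene, gt
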