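import numpy as np
import pytest

from boxnoise.synthetic import SceneConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 40-scene synthetic dataset shared by the cheaper integration tests."""
    return generate_dataset(SceneConfig(seed=11), 40)


@pytest.fixture(scope="session")
def study_dataset():
    """The 200-scene dataset used for the study-scale checks."""
    return generate_dataset(SceneConfig(seed=1), 200)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_box(rng, image_size=100.0, min_side=1.0, max_side=20.0):
    from boxnoise.annotations import BoundingBox
    w = rng.uniform(min_side, max_side)
    h = rng.uniform(min_side, max_side)
    x = rng.uniform(w / 2, image_size - w / 2)
    y = rng.uniform(h / 2, image_size - h / 2)
    return BoundingBox(x=x, y=y, w=w, h=h)
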