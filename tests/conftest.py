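import numpy as np
import pytest

import wetbird as wb


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_scene_cfg():
    """Scene configuration scaled to 96x96 used by fast pipeline tests."""
    return wb.SceneConfig(image_size=96, n_birds_range=(1, 5),
                          bird_area_fraction_range=(0.002, 0.01), seed=7)


@pytest.fixture(scope="session")
def tiny_samples(tiny_scene_cfg):
    return wb.generate_samples(12, tiny_scene_cfg)


def tiny_model(flags=None, width=0.0625, seed=0, nc=1):
    cfg = wb.ModelConfig(num_classes=nc, width_multiple=width,
                         flags=flags or wb.VariantFlags(), seed=seed)
    return wb.build_model(cfg)
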