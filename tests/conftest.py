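"""Shared fixtures: small, fast synthetic scenes rendered once per session."""

import numpy as np
import pytest

from leafgeom import SceneSpec, config_for_scene, render

# Desk-scale test rendering: 800 px wide, 2x supersampling, rectified at
# 6 px/mm keeps a full render+measure cycle under a second.
SMALL = dict(image_width_px=800, supersample=2)
SMALL_PPM = 6.0


@pytest.fixture(scope="session")
def small_square_scene():
    spec = SceneSpec(shape="square", **SMALL)
    image, truth = render(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def small_square_mask(small_square_scene):
    from leafgeom import PreprocessConfig, preprocess

    _, image, _ = small_square_scene
    return preprocess(image, PreprocessConfig(gauss_sigma=1.0))


@pytest.fixture(scope="session")
def small_config():
    return config_for_scene(SceneSpec(**SMALL), px_per_mm=SMALL_PPM)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
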