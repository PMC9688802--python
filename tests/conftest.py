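import numpy as np
import pytest
from hypothesis import settings

import spotquant as sq

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fig_model() -> sq.ResponseModel:
    """The printed logarithmic dose-response with the full 0-255 clamp."""
    return sq.ResponseModel()


@pytest.fixture(scope="session")
def default_scene() -> sq.SceneParams:
    return sq.SceneParams()


@pytest.fixture(scope="session")
def ramp_model(default_scene) -> sq.ResponseModel:
    """Dose-response clamped to the default scene's attainable range."""
    return sq.ramp_clamped_model(default_scene)


@pytest.fixture(scope="session")
def clean_scene() -> sq.SceneParams:
    """Noise-free, texture-free, evenly lit scene for exact checks."""
    return sq.SceneParams(noise_sd=0.0, texture_sd=0.0, illum_gradient=0.0)


@pytest.fixture(scope="session")
def segmented_spot(ramp_model, default_scene):
    """A default-conditions 5 mM spot, preprocessed and segmented."""
    image, truth = sq.simulate_spot(
        ramp_model, default_scene, 5.0, rng=np.random.default_rng(7)
    )
    pre = sq.preprocess(image)
    mask = sq.segment_spot(pre)
    return pre, mask, truth
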