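import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from hsicnn.synthetic import SceneConfig, make_scene, make_signatures, render_cube


@pytest.fixture(scope="session")
def tiny_scene():
    """A small 4-class scene shared by pipeline-level tests."""
    config = SceneConfig(rows=24, cols=24, bands=30, classes=4, seed=3)
    signatures = make_signatures(config)
    gt = make_scene(config)
    cube = render_cube(gt, signatures, config)
    return cube, gt, config


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
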