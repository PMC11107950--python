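import numpy as np
import pytest

import fundusmorph as fm


@pytest.fixture(scope="session")
def default_scene() -> fm.SyntheticScene:
    """One rendered right-eye scene with the default (realistic) geometry."""
    return fm.render_scene(fm.SceneTruth.default())


@pytest.fixture(scope="session")
def od_fit(default_scene) -> fm.EllipseFit:
    return fm.fit_ellipse(default_scene.masks.od)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
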