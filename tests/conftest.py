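import numpy as np
import pytest

from cellcoloc import RunConfig, SceneConfig, simulate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A 40-cell default-condition scene shared across read-only tests."""
    cfg = SceneConfig(n_cells=40, seed=11)
    truth, images = simulate_scene(cfg)
    return cfg, truth, images


@pytest.fixture(scope="session")
def analyzed_scene(small_scene):
    from cellcoloc import analyze

    cfg, truth, images = small_scene
    res = analyze(
        images["ref"], images["target"], phase_image=images["phase"],
        config=RunConfig(seed=5),
    )
    return truth, res


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
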