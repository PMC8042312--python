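import numpy as np
import pytest

from gazeforage import (
    DecisionParams,
    Landscape,
    Patch,
    PatchClass,
    SceneSpec,
    SimConfig,
    generate_scene,
)


def make_patch(pid, x, y, sd=30.0, value=0.2, klass=PatchClass.FACE, sd_y=None):
    sd_y = sd if sd_y is None else sd_y
    return Patch(
        id=pid, klass=klass, mu=np.array([x, y], dtype=float),
        sigma=np.diag([sd**2, sd_y**2]), value=value,
    )


def static_landscape(patches, frame_w=1280.0, frame_h=720.0, fps=30.0, duration_s=30.0):
    """Static landscape: the same patch set held for ``duration_s`` seconds."""
    n = max(int(round(duration_s * fps)), 1)
    return Landscape(frame_w=frame_w, frame_h=frame_h, fps=fps, frames=[list(patches)] * n)


@pytest.fixture
def two_patch_scene():
    """Two valued patches 240 px apart on a 1280x720 frame."""
    return static_landscape(
        [
            make_patch(1, 520, 360, value=0.5, klass=PatchClass.SPEAKER),
            make_patch(2, 760, 360, value=0.2),
        ]
    )


@pytest.fixture
def default_scene():
    return generate_scene(SceneSpec(), seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def params():
    return DecisionParams()


@pytest.fixture
def sim_config():
    return SimConfig()
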