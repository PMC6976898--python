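import numpy as np
import pytest

from palight.optics_db import OpticalProperties, TissueSpec
from palight.scene import Scene, SceneConfig, build_layered_scene


@pytest.fixture(scope="session")
def small_fibrous_scene():
    """36 mm cube at coarse pitch with mouse-thickness skin over fibrous bulk."""
    config = SceneConfig(
        bulk=TissueSpec("fibrous", 700),
        surface_layer=TissueSpec("skin", 700),
        skin_thickness=0.3,
        side_length=36.0,
        voxel_pitch=0.3,
    )
    return build_layered_scene(config)


def homogeneous_scene(mu_a, mu_s, g=0.0, n=1.4, side=24.0, pitch=0.3):
    """Single-material cube built directly (bypasses the tissue database)."""
    nvox = round(side / pitch)
    labels = np.zeros((nvox, nvox, nvox), dtype=np.uint8)
    props = OpticalProperties(mu_a=mu_a, mu_s=mu_s, g=g, n=n)
    config = SceneConfig(
        bulk=TissueSpec("fibrous", 700),
        surface_layer=TissueSpec("skin", 700),
        skin_thickness=0.0,
        side_length=side,
        voxel_pitch=pitch,
    )
    return Scene(labels=labels, palette=[props, props], config=config)
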