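"""Scene construction: layer geometry, source definition, launch sampling."""

import math

import numpy as np
import pytest

from palight.mc_engine import run
from palight.optics_db import TissueSpec, UnknownTissueError
from palight.scene import (
    SceneConfig,
    SourceSpec,
    build_layered_scene,
    build_phantom_scene,
    make_source,
)

from conftest import homogeneous_scene


def _config(skin, pitch, side=36.0, wl=700, bulk="fibrous"):
    return SceneConfig(
        bulk=TissueSpec(bulk, wl),
        surface_layer=TissueSpec("skin", wl),
        skin_thickness=skin,
        side_length=side,
        voxel_pitch=pitch,
    )


@pytest.mark.parametrize(
    "skin, pitch, side, n_vox, n_layers",
    [
        (0.3, 0.15, 36.0, 240, 2),
        (2.0, 0.05, 6.0, 120, 40),
        (0.3, 0.3, 36.0, 120, 1),
    ],
)
def test_layered_scene_geometry(skin, pitch, side, n_vox, n_layers):
    scene = build_layered_scene(_config(skin, pitch, side))
    assert scene.labels.shape == (n_vox, n_vox, n_vox)
    assert (scene.labels[:, :, :n_layers] == 1).all()
    assert (scene.labels[:, :, n_layers:] == 0).all()
    # volume composition identity
    assert int((scene.labels == 1).sum()) == n_layers * n_vox**2


def test_unresolvable_skin_layer_suggests_finer_pitch():
    with pytest.raises(ValueError, match="finer pitch"):
        _config(0.3, 0.5)


def test_side_must_be_whole_voxels():
    with pytest.raises(ValueError, match="whole number"):
        _config(0.3, 0.15, side=36.1)


def test_phantom_scene_milk_over_gelatin():
    scene = build_phantom_scene(voxel_pitch=0.5, side_length=36.0)
    n_layers = round(2.0 / 0.5)
    assert (scene.labels[:, :, :n_layers] == 1).all()
    assert scene.palette[1].n == pytest.approx(1.338)  # milk
    assert scene.palette[0].n == pytest.approx(1.5)    # gelatin
    assert scene.palette[0].mu_s == pytest.approx(0.05)


def test_phantom_zero_thickness_is_homogeneous_gelatin():
    scene = build_phantom_scene(skin_thickness=0.0, voxel_pitch=0.5)
    assert (scene.labels == 0).all()


def test_milk_outside_1064_is_a_lookup_error():
    with pytest.raises(UnknownTissueError):
        build_layered_scene(
            SceneConfig(
                bulk=TissueSpec("gelatin", 1064),
                surface_layer=TissueSpec("milk", 700),
                skin_thickness=2.0, side_length=36.0, voxel_pitch=0.5,
            )
        )


def test_source_direction_convention():
    straight = make_source(D=7, theta=0, n_photons=10, seed=0)
    assert np.allclose(straight.direction, [0, 0, 1])
    # the center ray crosses the imaging plane x=0 at depth D / tan(theta)
    for theta, d_expect in [(45.0, 7.0), (20.0, 7.0 / math.tan(math.radians(20)))]:
        src = make_source(D=7, theta=theta, n_photons=10, seed=0)
        dx, _, dz = src.direction
        crossing_depth = 7.0 / (-dx / dz)
        assert crossing_depth == pytest.approx(d_expect)
    assert 7.0 / math.tan(math.radians(20)) == pytest.approx(19.2, abs=0.05)


def test_source_validation():
    with pytest.raises(ValueError, match="imaging plane"):
        make_source(D=0.5, theta=45, n_photons=10, seed=0)  # D < width/2
    with pytest.raises(ValueError):
        make_source(D=7, theta=95, n_photons=10, seed=0)
    with pytest.raises(ValueError):
        SourceSpec(offset=7, theta=45, n_photons=0, seed=0)


def test_launch_positions_center_on_offset_footprint():
    """In vacuum with a straight-down beam, the entry-layer tally's center of
    mass recovers the footprint center (x = D, y = 0)."""
    scene = homogeneous_scene(mu_a=0.0, mu_s=0.0, side=24.0, pitch=0.3)
    src = make_source(D=4.0, theta=0.0, n_photons=20000, seed=3, length=10.0)
    grid = run(scene, src)
    top = grid.values[:, :, 0]
    nx, ny = top.shape
    xc = (np.arange(nx) + 0.5) * 0.3 - 12.0
    yc = (np.arange(ny) + 0.5) * 0.3 - 12.0
    w = top / top.sum()
    assert float((w.sum(axis=1) * xc).sum()) == pytest.approx(4.0, abs=0.05)
    assert float((w.sum(axis=0) * yc).sum()) == pytest.approx(0.0, abs=0.05)
    # footprint bounds respected: no energy outside x in [D-w/2, D+w/2]
    outside = (xc < 4.0 - 0.7 - 0.3) | (xc > 4.0 + 0.7 + 0.3)
    assert top[outside, :].sum() == 0.0
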