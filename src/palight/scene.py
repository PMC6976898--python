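"""Voxelized simulation volumes and the angled rectangular light source.

Geometry convention
-------------------
The volume is a cube of ``side_length`` mm.  Axes:

* ``z`` — depth from the tissue surface (z = 0 is the surface),
* ``y`` — along the transducer array (centered on 0),
* ``x`` — lateral offset from the imaging plane; the imaging plane is the
  mid-plane ``x = 0``.

A thin highly scattering surface layer (skin, or milk in the phantom) covers
the top of the volume; everything below is bulk tissue.  The light source is
a collimated rectangular emitter flush with the surface: footprint
``length × width`` (long axis along y) centered at ``(x = D, y = 0, z = 0)``,
emitting along the unit vector tilted ``theta`` degrees from the depth axis
toward the imaging plane (direction ``(-sin θ, 0, cos θ)``).  A beam launched
from the footprint center therefore crosses the imaging plane at depth
``D / tan θ``.

Only one source is built; left/right symmetry of the physical dual-bundle
probe is restored afterwards by mirror-averaging the fluence across x = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .optics_db import OpticalProperties, TissueSpec, get_properties

__all__ = [
    "Scene",
    "SceneConfig",
    "SourceSpec",
    "build_layered_scene",
    "build_phantom_scene",
    "make_source",
]

# Relative mismatch between requested and voxel-realizable layer thickness
# beyond which the scene is considered unresolvable at the chosen pitch.
_LAYER_ROUNDING_TOL = 0.25


@dataclass(frozen=True)
class SceneConfig:
    """Configuration of the layered volume.

    side_length and voxel_pitch are in mm.  skin_thickness is the surface
    layer thickness in mm (0.3 for mouse skin, 2.0 for human skin, 2.0 of
    milk for the phantom); it is snapped to a whole number of voxel layers.
    """

    bulk: TissueSpec
    surface_layer: TissueSpec
    skin_thickness: float
    side_length: float = 36.0
    voxel_pitch: float = 0.05

    def __post_init__(self) -> None:
        if self.voxel_pitch <= 0:
            raise ValueError("voxel_pitch must be positive")
        n = self.side_length / self.voxel_pitch
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValueError(
                f"side_length {self.side_length} mm is not a whole number of "
                f"voxels at pitch {self.voxel_pitch} mm"
            )
        if self.skin_thickness < 0:
            raise ValueError("skin_thickness must be >= 0")
        if self.skin_thickness > 0:
            layers = round(self.skin_thickness / self.voxel_pitch)
            if layers < 1:
                raise ValueError(
                    f"surface layer of {self.skin_thickness} mm is thinner than "
                    f"one voxel at pitch {self.voxel_pitch} mm; use a finer pitch"
                )
            realized = layers * self.voxel_pitch
            if abs(realized - self.skin_thickness) > _LAYER_ROUNDING_TOL * self.skin_thickness:
                raise ValueError(
                    f"surface layer of {self.skin_thickness} mm rounds to "
                    f"{realized} mm at pitch {self.voxel_pitch} mm; use a finer pitch"
                )

    @property
    def n_voxels(self) -> int:
        """Voxels per axis."""
        return round(self.side_length / self.voxel_pitch)

    @property
    def n_surface_layers(self) -> int:
        """Number of top z-layers occupied by the surface tissue."""
        if self.skin_thickness == 0:
            return 0
        return round(self.skin_thickness / self.voxel_pitch)


@dataclass
class Scene:
    """A voxel label grid plus its label → optical-properties palette.

    ``labels`` is indexed ``[ix, iy, iz]`` with the axes convention of the
    module docstring; ``palette[k]`` gives the properties of label value k.
    """

    labels: np.ndarray
    palette: list[OpticalProperties]
    config: SceneConfig

    def __post_init__(self) -> None:
        if self.labels.max(initial=0) >= len(self.palette):
            raise ValueError("label grid references palette entries that do not exist")

    @property
    def pitch(self) -> float:
        return self.config.voxel_pitch

    @property
    def side(self) -> float:
        return self.config.side_length

    def depth_axis(self) -> np.ndarray:
        """Voxel-center depths (mm) for each z-layer."""
        p = self.pitch
        return (np.arange(self.labels.shape[2]) + 0.5) * p

    def property_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Palette unpacked into per-label (mu_a, mu_s, g, n) float arrays."""
        mu_a = np.array([p.mu_a for p in self.palette])
        mu_s = np.array([p.mu_s for p in self.palette])
        g = np.array([p.g for p in self.palette])
        n = np.array([p.n for p in self.palette])
        return mu_a, mu_s, g, n

    def with_scaled_surface_mu_s(self, scale: float) -> "Scene":
        """Copy of the scene with the surface layer's mu_s multiplied by scale.

        Used for the ballistic-vs-diffusive skin-scattering sections.  With no
        surface layer the scene is returned unchanged.
        """
        if scale <= 0:
            raise ValueError("scale must be positive")
        if self.config.n_surface_layers == 0 or scale == 1.0:
            return Scene(self.labels, list(self.palette), self.config)
        surf = self.palette[1]
        palette = list(self.palette)
        palette[1] = OpticalProperties(surf.mu_a, surf.mu_s * scale, surf.g, surf.n)
        return Scene(self.labels, palette, self.config)


@dataclass(frozen=True)
class SourceSpec:
    """Collimated rectangular emitter on the volume's top face.

    offset is D, the distance (mm) from the imaging plane to the footprint
    center; theta is the tilt (degrees) of the emission direction away from
    the depth axis, toward the imaging plane.
    """

    offset: float
    theta: float
    n_photons: int
    seed: int
    length: float = 25.0
    width: float = 1.4

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta < 90.0:
            raise ValueError(f"theta must be in [0, 90) deg, got {self.theta}")
        if self.offset < self.width / 2:
            raise ValueError(
                f"offset D={self.offset} mm would put the footprint across the "
                f"imaging plane (width {self.width} mm)"
            )
        if self.n_photons <= 0:
            raise ValueError("n_photons must be positive")

    @property
    def direction(self) -> np.ndarray:
        """Unit emission direction (x, y, z): tilted θ from +z toward −x."""
        th = math.radians(self.theta)
        return np.array([-math.sin(th), 0.0, math.cos(th)])

    def fits_in(self, config: SceneConfig) -> bool:
        half = config.side_length / 2
        return (
            self.offset + self.width / 2 <= half
            and self.length / 2 <= half
        )


def _build(config: SceneConfig) -> Scene:
    n = config.n_voxels
    labels = np.zeros((n, n, n), dtype=np.uint8)
    palette = [get_properties(config.bulk)]
    k = config.n_surface_layers
    if k > 0:
        palette.append(get_properties(config.surface_layer))
        labels[:, :, :k] = 1
    else:
        # keep palette slot 1 pointing at the (unused) surface material so
        # with_scaled_surface_mu_s stays well-defined
        palette.append(get_properties(config.surface_layer))
    return Scene(labels=labels, palette=palette, config=config)


def build_layered_scene(config: SceneConfig) -> Scene:
    """Skin-over-bulk tissue volume (mouse: 0.3 mm skin, human: 2.0 mm)."""
    return _build(config)


def build_phantom_scene(
    skin_thickness: float = 2.0,
    side_length: float = 36.0,
    voxel_pitch: float = 0.05,
) -> Scene:
    """Milk-over-gelatin phantom volume at 1064 nm.

    A 2 mm milk coupling layer (standing in for skin-like scattering) over a
    gelatin bulk whose absorption/scattering approximate water.
    """
    config = SceneConfig(
        bulk=TissueSpec("gelatin", 1064),
        surface_layer=TissueSpec("milk", 1064),
        skin_thickness=skin_thickness,
        side_length=side_length,
        voxel_pitch=voxel_pitch,
    )
    return _build(config)


def make_source(
    D: float,
    theta: float,
    n_photons: int,
    seed: int,
    length: float = 25.0,
    width: float = 1.4,
) -> SourceSpec:
    """Build the standard probe source at offset D (mm) and angle theta (deg)."""
    return SourceSpec(
        offset=D, theta=theta, n_photons=n_photons, seed=seed,
        length=length, width=width,
    )
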