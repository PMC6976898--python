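"""Study orchestration: angle/distance sweeps and the species-ratio factorial.

The study design, for each (species skin thickness, bulk tissue, wavelength)
condition:

* an **angle sweep** — emission angle 20 to 70 deg in 12.5-deg steps at a
  fixed source offset D = 7 mm,
* a **distance sweep** — D = 5 to 13 mm in 2 mm steps at a fixed 45-deg
  angle,

each reduced to the ROI depth profile and its peak.  The translation
statistic is the ratio of maximum fluence (max over the angle grid of the
profile peak) between the 0.3-mm-skin (mouse) and 2.0-mm-skin (human) runs,
computed per tissue/wavelength over purely fatty and purely fibrous bulk at
700/800/900/1064 nm and fatty/fibrous mixtures at 800 nm.

Every condition draws its own seed from the master seed, so conditions are
statistically independent and individually reproducible.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics
from .mc_engine import FluenceGrid, mirror_average, run
from .optics_db import TissueSpec
from .scene import Scene, SceneConfig, build_layered_scene, make_source

__all__ = [
    "DESK_PRESET",
    "FULL_PRESET",
    "StudyPlan",
    "SweepResult",
    "condition_seed",
    "fluence_section",
    "run_angle_sweep",
    "run_distance_sweep",
    "run_full_study",
    "simulate_condition",
    "study_tissues",
]

log = logging.getLogger(__name__)

SPECIES_SKIN_MM = {"mouse": 0.3, "human": 2.0}


@dataclass(frozen=True)
class StudyPlan:
    """Grids, budgets and seed policy for the full simulation study."""

    angles: tuple[float, ...] = (20.0, 32.5, 45.0, 57.5, 70.0)
    distances: tuple[float, ...] = (5.0, 7.0, 9.0, 11.0, 13.0)
    angle_sweep_D: float = 7.0
    distance_sweep_theta: float = 45.0
    side_length: float = 36.0
    voxel_pitch: float = 0.15
    n_photons: int = 10_000_000
    master_seed: int = 0
    wavelengths: tuple[int, ...] = (700, 800, 900, 1064)
    mixed_fractions: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)

    def __post_init__(self) -> None:
        if not self.angles or not self.distances:
            raise ValueError("angle and distance grids must be non-empty")

    def with_photons(self, n_photons: int) -> "StudyPlan":
        return replace(self, n_photons=n_photons)

    def with_seed(self, master_seed: int) -> "StudyPlan":
        return replace(self, master_seed=master_seed)


#: The paper-scale study configuration: 50 um voxels, 1e9 photons/condition.
FULL_PRESET = StudyPlan(voxel_pitch=0.05, n_photons=1_000_000_000)

#: Desk-scale configuration: 0.15 mm voxels, 1e7 photons/condition.
DESK_PRESET = StudyPlan(voxel_pitch=0.15, n_photons=10_000_000)

PRESETS = {"desk": DESK_PRESET, "full": FULL_PRESET}


def condition_seed(master_seed: int, *parts) -> int:
    """Stable per-condition seed derived from the master seed.

    Hash-based so each (species, tissue, wavelength, parameter) condition has
    an independent, order-insensitive stream.
    """
    key = "|".join([str(master_seed), *map(str, parts)])
    digest = hashlib.blake2b(key.encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def study_tissues(plan: StudyPlan) -> list[TissueSpec]:
    """The bulk-tissue factorial: fatty and fibrous at every wavelength,
    plus the mixed fractions at 800 nm."""
    specs = [TissueSpec(kind, wl)
             for kind in ("fatty", "fibrous") for wl in plan.wavelengths]
    specs += [TissueSpec("mixed", 800, fatty_fraction=f)
              for f in plan.mixed_fractions]
    return specs


def _scene_for(tissue: TissueSpec, skin_thickness: float,
               plan: StudyPlan) -> Scene:
    config = SceneConfig(
        bulk=tissue,
        surface_layer=TissueSpec("skin", tissue.wavelength),
        skin_thickness=skin_thickness,
        side_length=plan.side_length,
        voxel_pitch=plan.voxel_pitch,
    )
    return build_layered_scene(config)


def simulate_condition(
    tissue: TissueSpec,
    skin_thickness: float,
    D: float,
    theta: float,
    plan: StudyPlan,
    seed: int | None = None,
    skin_mu_s_scale: float = 1.0,
) -> FluenceGrid:
    """One mirrored fluence grid for a single geometry/tissue condition."""
    if seed is None:
        seed = condition_seed(plan.master_seed, tissue.label,
                              skin_thickness, D, theta)
    scene = _scene_for(tissue, skin_thickness, plan)
    if skin_mu_s_scale != 1.0:
        scene = scene.with_scaled_surface_mu_s(skin_mu_s_scale)
    source = make_source(D=D, theta=theta, n_photons=plan.n_photons, seed=seed)
    t0 = time.perf_counter()
    grid = run(scene, source)
    log.info(
        "condition %s skin=%.2gmm D=%.3g theta=%.3g: %d photons in %.1fs",
        tissue.label, skin_thickness, D, theta, plan.n_photons,
        time.perf_counter() - t0,
    )
    return mirror_average(grid)


@dataclass
class SweepResult:
    """Per-grid-point peaks and profiles for one swept condition."""

    table: pd.DataFrame               # columns: param, peak, peak_depth
    profiles: dict[float, metrics.DepthProfile]
    param: str                        # "theta_deg" or "D_mm"
    tissue: TissueSpec
    skin_thickness: float

    @property
    def peaks(self) -> np.ndarray:
        return self.table["peak"].to_numpy()

    def argmax_param(self) -> float:
        """Grid value with the highest peak fluence."""
        return float(self.table.loc[self.table["peak"].idxmax(), self.param])


def _sweep(tissue, skin_thickness, plan, values, param) -> SweepResult:
    rows = []
    profiles = {}
    for v in values:
        if param == "theta_deg":
            D, theta = plan.angle_sweep_D, v
        else:
            D, theta = v, plan.distance_sweep_theta
        grid = simulate_condition(tissue, skin_thickness, D, theta, plan)
        prof = metrics.depth_profile(grid)
        peak, depth = metrics.peak_fluence(prof)
        rows.append({param: v, "peak": peak, "peak_depth_mm": depth})
        profiles[v] = prof
    return SweepResult(
        table=pd.DataFrame(rows), profiles=profiles, param=param,
        tissue=tissue, skin_thickness=skin_thickness,
    )


def run_angle_sweep(tissue: TissueSpec, skin_thickness: float,
                    plan: StudyPlan) -> SweepResult:
    """Sweep the emission angle at fixed D (profile + peak per angle)."""
    return _sweep(tissue, skin_thickness, plan, plan.angles, "theta_deg")


def run_distance_sweep(tissue: TissueSpec, skin_thickness: float,
                       plan: StudyPlan) -> SweepResult:
    """Sweep the source offset D at the fixed 45-deg angle."""
    return _sweep(tissue, skin_thickness, plan, plan.distances, "D_mm")


@dataclass
class StudyResult:
    """Output of the full factorial: ratio matrix plus all sweep tables."""

    ratios: pd.DataFrame
    sweeps: dict[tuple[str, str], SweepResult] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)


def run_full_study(plan: StudyPlan,
                   tissues: list[TissueSpec] | None = None) -> StudyResult:
    """Angle sweeps for every condition and species, reduced to the
    mouse/human maximum-fluence ratio matrix.

    Per-condition failures are recorded and skipped so one bad condition
    does not abort the study.
    """
    tissues = tissues if tissues is not None else study_tissues(plan)
    rows = []
    sweeps: dict[tuple[str, str], SweepResult] = {}
    failures: dict[str, str] = {}
    for tissue in tissues:
        try:
            per_species = {}
            for species, thickness in SPECIES_SKIN_MM.items():
                res = run_angle_sweep(tissue, thickness, plan)
                sweeps[(species, tissue.label)] = res
                per_species[species] = res
            ratio = metrics.species_ratio(
                per_species["mouse"].peaks, per_species["human"].peaks)
            rows.append({
                "tissue": tissue.kind,
                "wavelength_nm": tissue.wavelength,
                "fatty_fraction": tissue.fatty_fraction,
                "ratio": ratio,
                "mouse_argmax_deg": per_species["mouse"].argmax_param(),
                "human_argmax_deg": per_species["human"].argmax_param(),
            })
        except Exception as exc:  # noqa: BLE001 - study must continue
            log.error("condition %s failed: %s", tissue.label, exc)
            failures[tissue.label] = str(exc)
    return StudyResult(ratios=pd.DataFrame(rows), sweeps=sweeps,
                       failures=failures)


def fluence_section(
    tissue: TissueSpec,
    skin_thickness: float,
    theta: float,
    plan: StudyPlan,
    skin_mu_s_scale: float = 1.0,
    D: float | None = None,
) -> dict:
    """2-D fluence section perpendicular to the imaging plane (x-z at y = 0).

    With ``skin_mu_s_scale < 1`` the skin scatters less, preserving the
    ballistic directionality of the tilted beam through the layer; at the
    nominal scattering the thick layer diffuses it.  Returns the section,
    its mm extent, and the ROI depth-profile peak for quantitative
    comparison.
    """
    if skin_mu_s_scale <= 0:
        raise ValueError("skin_mu_s_scale must be positive")
    D = plan.angle_sweep_D if D is None else D
    grid = simulate_condition(tissue, skin_thickness, D, theta, plan,
                              skin_mu_s_scale=skin_mu_s_scale)
    ny = grid.values.shape[1]
    section = grid.values[:, ny // 2, :]
    prof = metrics.depth_profile(grid)
    peak, peak_depth = metrics.peak_fluence(prof)
    half = plan.side_length / 2
    return {
        "section": section,
        "extent_mm": (-half, half, plan.side_length, 0.0),
        "peak": peak,
        "peak_depth_mm": peak_depth,
    }
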