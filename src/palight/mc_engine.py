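"""Monte Carlo photon transport: energy-normalized fluence on the voxel grid.

The heavy lifting happens in the compiled kernel (:mod:`palight._transport`);
this module owns the public surface: :func:`run` produces a
:class:`FluenceGrid` (fluence per voxel per unit delivered energy, units
1/mm^2, with an energy ledger), :func:`mirror_average` restores the
probe's left/right symmetry, and the small sampling primitives
(:func:`sample_hg`, :func:`roulette`, :func:`step_and_tally`) are exposed
both for reuse and so their statistical properties can be tested in
isolation.  A slow pure-Python engine (:func:`run_reference`) implements the
same transport rules independently of the compiled kernel and serves as a
cross-check at small photon counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._transport import transport_kernel
from .scene import Scene, SourceSpec

__all__ = [
    "FluenceGrid",
    "PhotonState",
    "mirror_average",
    "roulette",
    "run",
    "run_reference",
    "sample_hg",
    "step_and_tally",
]

W_MIN = 1e-4
P_SURVIVE = 0.1


@dataclass
class PhotonState:
    """Transport state of one weighted photon packet."""

    position: np.ndarray   # mm, internal corner-origin coordinates
    direction: np.ndarray  # unit vector
    weight: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = float(np.linalg.norm(self.direction))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"direction must be a unit vector, |d| = {norm}")
        if self.weight <= 0:
            raise ValueError("weight must be positive")


@dataclass
class FluenceGrid:
    """Energy-normalized fluence tally with its conservation ledger.

    ``values[ix, iy, iz]`` is fluence per unit delivered energy (1/mm^2) in
    the voxel; the ledger tracks where the launched unit weights went.
    Conservation: launched = absorbed + escaped + roulette_net + residual
    (roulette_net is the signed weight destroyed/created by Russian roulette
    and is small; residual is the weight of any forcibly terminated photons).
    """

    values: np.ndarray
    pitch: float
    ledger: dict[str, float]
    provenance: dict = field(default_factory=dict)

    @property
    def voxel_volume(self) -> float:
        return self.pitch ** 3

    def conservation_error(self) -> float:
        """|launched - (absorbed + escaped + roulette_net + residual)| / launched."""
        led = self.ledger
        closed = (
            led["absorbed"] + led["escaped"] + led["roulette_net"] + led["residual"]
        )
        return abs(led["launched"] - closed) / led["launched"]


def run(scene: Scene, source: SourceSpec) -> FluenceGrid:
    """Trace ``source.n_photons`` photons through ``scene``.

    Deterministic given (scene, source, seed).  Photons crossing any outer
    face permanently escape.  The returned fluence is normalized to the total
    launched energy.
    """
    if not source.fits_in(scene.config):
        raise ValueError(
            f"source footprint (D={source.offset}, {source.length}x{source.width} mm) "
            f"does not fit inside the {scene.side} mm top face"
        )
    mu_a, mu_s, g, n = scene.property_arrays()
    tally = np.zeros_like(scene.labels, dtype=np.float64)
    half = scene.side / 2.0
    th = math.radians(source.theta)
    absorbed, escaped, roulette_net, residual = transport_kernel(
        scene.labels,
        mu_a, mu_s, g, n,
        scene.pitch,
        half + source.offset,  # footprint center x (internal coords)
        half,                  # footprint center y
        source.width / 2.0,
        source.length / 2.0,
        -math.sin(th), math.cos(th),
        source.n_photons,
        np.uint64(source.seed),
        W_MIN, P_SURVIVE,
        tally,
    )
    n_ph = float(source.n_photons)
    values = tally / (scene.pitch ** 3 * n_ph)
    ledger = {
        "launched": n_ph,
        "absorbed": absorbed,
        "escaped": escaped,
        "roulette_net": roulette_net,
        "residual": residual,
    }
    provenance = {
        "scene": {
            "bulk": scene.config.bulk.label,
            "surface": scene.config.surface_layer.label,
            "skin_thickness_mm": scene.config.skin_thickness,
            "side_mm": scene.side,
            "pitch_mm": scene.pitch,
        },
        "source": {
            "D_mm": source.offset,
            "theta_deg": source.theta,
            "footprint_mm": [source.length, source.width],
            "n_photons": source.n_photons,
            "seed": source.seed,
        },
    }
    return FluenceGrid(values=values, pitch=scene.pitch, ledger=ledger,
                       provenance=provenance)


def mirror_average(grid: FluenceGrid) -> FluenceGrid:
    """Average the fluence with its mirror image across the imaging plane.

    The imaging plane is the x mid-plane; the x axis must contain an even
    number of voxels so the plane coincides with a voxel face.
    """
    nx = grid.values.shape[0]
    if nx % 2 != 0:
        raise ValueError(
            f"x axis has {nx} voxels; mirror averaging needs the imaging plane "
            "on a voxel face (even voxel count)"
        )
    values = 0.5 * (grid.values + grid.values[::-1, :, :])
    return FluenceGrid(values=values, pitch=grid.pitch,
                       ledger=dict(grid.ledger),
                       provenance={**grid.provenance, "mirrored": True})


def sample_hg(g: float, rng: np.random.Generator, size=None):
    """Sample cos(deflection angle) from the Henyey-Greenstein distribution.

    E[cos] = g; g = 0 reduces to the isotropic case (uniform cosine).
    """
    if not -1.0 < g < 1.0:
        raise ValueError(f"g must be in (-1, 1), got {g}")
    u = rng.random(size)
    if abs(g) < 1e-6:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return np.clip((1.0 + g * g - tmp * tmp) / (2.0 * g), -1.0, 1.0)


def roulette(
    state: PhotonState,
    rng: np.random.Generator,
    w_min: float = W_MIN,
    p_survive: float = P_SURVIVE,
) -> Optional[PhotonState]:
    """Russian roulette: unbiased termination of low-weight photons.

    States at or above ``w_min`` pass through unchanged.  Below it, the
    photon survives with probability ``p_survive`` (weight boosted by
    1/p_survive) and is otherwise terminated (returns None).
    """
    if state.weight >= w_min:
        return state
    if rng.random() < p_survive:
        return PhotonState(state.position, state.direction,
                           state.weight / p_survive)
    return None


def _deflect(direction: np.ndarray, ct: float, phi: float) -> np.ndarray:
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    ux, uy, uz = direction
    cp, sp = math.cos(phi), math.sin(phi)
    if abs(uz) > 0.99999:
        new = np.array([st * cp, st * sp, math.copysign(ct, uz)])
    else:
        den = math.sqrt(1.0 - uz * uz)
        new = np.array([
            st * (ux * uz * cp - uy * sp) / den + ux * ct,
            st * (uy * uz * cp + ux * sp) / den + uy * ct,
            -den * st * cp + uz * ct,
        ])
    return new / np.linalg.norm(new)


def step_and_tally(
    state: PhotonState,
    scene: Scene,
    rng: np.random.Generator,
    tally: np.ndarray | None = None,
) -> Optional[PhotonState]:
    """One transport hop of the reference (pure-Python) engine.

    Propagates the photon to its next scattering event, traversing voxels
    and re-accumulating the sampled optical depth where mu_s changes,
    depositing the exponentially weighted track length in ``tally`` (weighted
    path length; divide by voxel volume for fluence) and attenuating the
    weight by exp(-mu_a * l) per segment.  Returns the post-scattering state,
    or None if the photon escaped the volume.  Refractive-index mismatches
    between voxels are handled with Fresnel reflection / Snell refraction.
    """
    mu_a_tab, mu_s_tab, g_tab, n_tab = scene.property_arrays()
    pitch = scene.pitch
    shape = scene.labels.shape
    pos = state.position.copy()
    d = state.direction.copy()
    w = state.weight
    idx = np.minimum(np.maximum((pos / pitch).astype(int), 0),
                     np.array(shape) - 1)
    tau = -math.log(rng.random())

    while True:
        lab = scene.labels[idx[0], idx[1], idx[2]]
        ma, ms = mu_a_tab[lab], mu_s_tab[lab]
        # distance to each face
        t_face = np.full(3, np.inf)
        for a in range(3):
            if d[a] > 1e-12:
                t_face[a] = ((idx[a] + 1) * pitch - pos[a]) / d[a]
            elif d[a] < -1e-12:
                t_face[a] = (idx[a] * pitch - pos[a]) / d[a]
        axis = int(np.argmin(t_face))
        tb = max(t_face[axis], 0.0)
        ts = tau / ms if ms > 0 else np.inf
        ell = min(ts, tb)

        if ma > 0:
            em1 = -math.expm1(-ma * ell)
            if tally is not None:
                tally[idx[0], idx[1], idx[2]] += w * em1 / ma
            w *= 1.0 - em1
        elif tally is not None:
            tally[idx[0], idx[1], idx[2]] += w * ell

        pos = pos + ell * d
        if ts <= tb:
            ct = float(sample_hg(g_tab[lab], rng)) if g_tab[lab] != 0 \
                else 2.0 * rng.random() - 1.0
            d = _deflect(d, ct, 2.0 * math.pi * rng.random())
            return PhotonState(pos, d, w)

        tau -= tb * ms
        step = 1 if d[axis] > 0 else -1
        pos[axis] = (idx[axis] + 1) * pitch if step == 1 else idx[axis] * pitch
        nxt = idx.copy()
        nxt[axis] += step
        if nxt[axis] < 0 or nxt[axis] >= shape[axis]:
            return None  # escaped
        lab2 = scene.labels[nxt[0], nxt[1], nxt[2]]
        n1, n2 = n_tab[lab], n_tab[lab2]
        if n1 != n2:
            ci = abs(d[axis])
            ratio = n1 / n2
            sin2t = ratio * ratio * (1.0 - ci * ci)
            if sin2t >= 1.0:
                d[axis] = -d[axis]
                continue
            ct2 = math.sqrt(1.0 - sin2t)
            rs = (n1 * ci - n2 * ct2) / (n1 * ci + n2 * ct2)
            rp = (n1 * ct2 - n2 * ci) / (n1 * ct2 + n2 * ci)
            if rng.random() < 0.5 * (rs * rs + rp * rp):
                d[axis] = -d[axis]
                continue
            sgn = math.copysign(1.0, d[axis])
            d = d * ratio
            d[axis] = sgn * ct2
            d /= np.linalg.norm(d)
        idx = nxt


def run_reference(
    scene: Scene,
    source: SourceSpec,
    rng: np.random.Generator | None = None,
    max_hops: int = 100_000,
) -> FluenceGrid:
    """Pure-Python engine implementing the same transport rules as :func:`run`.

    Orders of magnitude slower than the compiled kernel; intended for
    cross-validation at small photon counts.
    """
    if rng is None:
        rng = np.random.default_rng(source.seed)
    tally = np.zeros_like(scene.labels, dtype=np.float64)
    half = scene.side / 2.0
    direction = source.direction
    absorbed = escaped = roulette_net = residual = 0.0

    for _ in range(source.n_photons):
        x = half + source.offset + (rng.random() - 0.5) * source.width
        y = half + (rng.random() - 0.5) * source.length
        state: Optional[PhotonState] = PhotonState(
            np.array([x, y, 0.0]), direction.copy(), 1.0)
        for _hop in range(max_hops):
            assert state is not None
            nxt = step_and_tally(state, scene, rng, tally)
            if nxt is None:
                # crossed an outer face with whatever weight survived en route
                break
            state = nxt
            if state.weight < W_MIN:
                survived = roulette(state, rng)
                if survived is None:
                    roulette_net += state.weight
                    state = None
                    break
                roulette_net -= survived.weight - state.weight
                state = survived
        else:
            residual += state.weight
            state = None

    # under this estimator absorbed energy is identically mu_a * tally;
    # the escaped weight then follows from conservation
    mu_a_by_label = np.array([p.mu_a for p in scene.palette])
    absorbed = float(np.sum(tally * mu_a_by_label[scene.labels]))
    escaped = source.n_photons - absorbed - roulette_net - residual
    values = tally / (scene.pitch ** 3 * source.n_photons)
    return FluenceGrid(values=values, pitch=scene.pitch, ledger={
        "launched": float(source.n_photons),
        "absorbed": absorbed,
        "escaped": escaped,
        "roulette_net": roulette_net,
        "residual": residual,
    })
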