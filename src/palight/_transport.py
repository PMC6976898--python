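"""Compiled voxel photon-transport kernel.

Transport model (steady-state, weighted photons):

* Distances between scattering events are sampled against the scattering
  coefficient only: an exponential optical depth ``tau ~ Exp(1)`` is consumed
  as ``mu_s * path`` and re-accumulated across voxels whose ``mu_s`` differs
  (voxel-by-voxel digital traversal).
* Absorption is continuous: over a segment of length ``l`` in a voxel the
  weight is attenuated by ``exp(-mu_a * l)`` and the fluence tally receives
  the exponentially weighted track length ``w * (1 - exp(-mu_a * l)) / mu_a``
  (plain ``w * l`` when ``mu_a = 0``).  The energy absorbed in the segment is
  exactly ``mu_a`` times the tallied fluence contribution times the voxel
  volume, so the absorbed-energy ledger closes by construction.
* Scattering deflections follow the Henyey-Greenstein phase function with the
  local anisotropy g; azimuth is uniform.
* Refractive-index mismatches between adjacent voxels are handled with Snell
  refraction and unpolarized Fresnel reflection at the shared face; photons
  crossing any outer face of the volume permanently escape.
* Photons whose weight falls below ``w_min`` undergo Russian roulette
  (survival probability ``p_survive``, survivor weight divided by
  ``p_survive``); the net weight created/destroyed by roulette is ledgered so
  launched = absorbed + escaped + roulette_net + residual holds exactly.

The RNG is a counter-based splitmix64: every photon derives its own stream
from (seed, photon index), so results are independent of execution order.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit, uint64

_U64 = np.uint64
_INV_2_53 = 1.0 / 9007199254740992.0

MAX_SEGMENTS_PER_PHOTON = 2_000_000


@njit(cache=True, inline="always")
def _rng_next(state):
    """Advance a splitmix64 state; return (new_state, uniform in [0, 1))."""
    state = state + uint64(0x9E3779B97F4A7C15)
    z = state
    z = (z ^ (z >> uint64(30))) * uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> uint64(27))) * uint64(0x94D049BB133111EB)
    z = z ^ (z >> uint64(31))
    return state, float(z >> uint64(11)) * _INV_2_53


@njit(cache=True, inline="always")
def _photon_stream(seed, pid):
    s = (uint64(seed) + uint64(1)) * uint64(0xD2B74407B1CE6E93)
    s = s ^ ((uint64(pid) + uint64(1)) * uint64(0x9E3779B97F4A7C15))
    s, _ = _rng_next(s)
    return s


@njit(cache=True, inline="always")
def _sample_hg_cos(g, u):
    if g > 1e-6 or g < -1e-6:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
    else:
        ct = 2.0 * u - 1.0
    return ct


@njit(cache=True, fastmath=True)
def transport_kernel(
    labels,          # uint8 [nx, ny, nz]
    mua, mus, gg, nn,  # float64 per-label property arrays
    pitch,           # voxel pitch, mm
    src_cx, src_cy,  # footprint center (internal coords, mm)
    half_wid, half_len,  # footprint half extents along x and y, mm
    dir0x, dir0z,    # initial direction (y component is 0)
    n_photons, seed,
    w_min, p_survive,
    tally,           # float64 [nx, ny, nz], accumulates weighted track length
):
    """Trace n_photons through the labelled volume, accumulating the tally.

    Returns (absorbed, escaped, roulette_net, residual) total weights.
    The tally holds weighted path length; divide by (voxel volume * photons)
    to obtain fluence per unit delivered energy.
    """
    nx, ny, nz = labels.shape
    inv_p = 1.0 / pitch
    big = 1e30

    absorbed = 0.0
    escaped = 0.0
    roulette_net = 0.0
    residual = 0.0

    for pid in range(n_photons):
        s = _photon_stream(seed, pid)
        s, u1 = _rng_next(s)
        s, u2 = _rng_next(s)
        x = src_cx + (2.0 * u1 - 1.0) * half_wid
        y = src_cy + (2.0 * u2 - 1.0) * half_len
        z = 0.0
        ix = int(x * inv_p)
        iy = int(y * inv_p)
        iz = 0
        if ix < 0:
            ix = 0
        elif ix >= nx:
            ix = nx - 1
        if iy < 0:
            iy = 0
        elif iy >= ny:
            iy = ny - 1

        ux = dir0x
        uy = 0.0
        uz = dir0z
        # cached reciprocal direction components (refreshed on deflection)
        rx = 1.0 / ux if (ux > 1e-12 or ux < -1e-12) else big
        ry = big
        rz = 1.0 / uz if (uz > 1e-12 or uz < -1e-12) else big
        w = 1.0
        s, u = _rng_next(s)
        tau = -math.log(u) if u > 0.0 else big

        nseg = 0
        while True:
            nseg += 1
            if nseg > MAX_SEGMENTS_PER_PHOTON:
                residual += w
                break

            lab = labels[ix, iy, iz]
            ma = mua[lab]
            ms = mus[lab]

            # distances to the voxel faces along the current direction
            # negative distances: a tiny negative means FP overshoot of a
            # face (treat as 0, cross now); a huge negative comes from the
            # sentinel reciprocal of a ~zero component (no crossing).
            if ux > 0.0:
                tx = ((ix + 1) * pitch - x) * rx
            else:
                tx = (ix * pitch - x) * rx
            if tx < 0.0:
                tx = big if tx < -1e9 else 0.0
            if uy > 0.0:
                ty = ((iy + 1) * pitch - y) * ry
            else:
                ty = (iy * pitch - y) * ry
            if ty < 0.0:
                ty = big if ty < -1e9 else 0.0
            if uz > 0.0:
                tz = ((iz + 1) * pitch - z) * rz
            else:
                tz = (iz * pitch - z) * rz
            if tz < 0.0:
                tz = big if tz < -1e9 else 0.0

            axis = 0
            tb = tx
            if ty < tb:
                tb = ty
                axis = 1
            if tz < tb:
                tb = tz
                axis = 2
            if tb < 0.0:
                tb = 0.0

            scatter_here = False
            if ms > 0.0:
                ts = tau / ms
                if ts <= tb:
                    ell = ts
                    scatter_here = True
                else:
                    ell = tb
            else:
                ell = tb

            # tally the segment and attenuate the weight
            if ma > 1e-14:
                xr = ma * ell
                if xr < 1e-3:
                    # 1 - exp(-xr) to third order; relative error < 1e-12 here
                    em1 = xr * (1.0 - 0.5 * xr * (1.0 - xr / 3.0))
                else:
                    em1 = -math.expm1(-xr)
                tally[ix, iy, iz] += w * em1 / ma
                absorbed += w * em1
                w *= 1.0 - em1
            else:
                tally[ix, iy, iz] += w * ell

            if scatter_here:
                x += ell * ux
                y += ell * uy
                z += ell * uz
                # Henyey-Greenstein deflection about the current direction
                g = gg[lab]
                s, u = _rng_next(s)
                ct = _sample_hg_cos(g, u)
                st = math.sqrt(max(0.0, 1.0 - ct * ct))
                s, u = _rng_next(s)
                phi = 2.0 * math.pi * u
                cp = math.cos(phi)
                sp = math.sin(phi)
                if uz > 0.99999 or uz < -0.99999:
                    ux = st * cp
                    uy = st * sp
                    uz = ct if uz > 0.0 else -ct
                else:
                    den = math.sqrt(1.0 - uz * uz)
                    nux = st * (ux * uz * cp - uy * sp) / den + ux * ct
                    nuy = st * (uy * uz * cp + ux * sp) / den + uy * ct
                    nuz = -den * st * cp + uz * ct
                    ux, uy, uz = nux, nuy, nuz
                norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                ux /= norm
                uy /= norm
                uz /= norm
                rx = 1.0 / ux if (ux > 1e-12 or ux < -1e-12) else big
                ry = 1.0 / uy if (uy > 1e-12 or uy < -1e-12) else big
                rz = 1.0 / uz if (uz > 1e-12 or uz < -1e-12) else big
                s, u = _rng_next(s)
                tau = -math.log(u) if u > 0.0 else big
                if w < w_min:
                    s, u = _rng_next(s)
                    if u < p_survive:
                        roulette_net -= w * (1.0 / p_survive - 1.0)
                        w /= p_survive
                    else:
                        roulette_net += w
                        break
            else:
                # advance to the crossed face and step the voxel index
                tau -= tb * ms
                if tau < 0.0:
                    tau = 0.0
                x += tb * ux
                y += tb * uy
                z += tb * uz
                if axis == 0:
                    step = 1 if ux > 0.0 else -1
                    x = (ix + 1) * pitch if step == 1 else ix * pitch
                    jx, jy, jz = ix + step, iy, iz
                elif axis == 1:
                    step = 1 if uy > 0.0 else -1
                    y = (iy + 1) * pitch if step == 1 else iy * pitch
                    jx, jy, jz = ix, iy + step, iz
                else:
                    step = 1 if uz > 0.0 else -1
                    z = (iz + 1) * pitch if step == 1 else iz * pitch
                    jx, jy, jz = ix, iy, iz + step

                if jx < 0 or jx >= nx or jy < 0 or jy >= ny or jz < 0 or jz >= nz:
                    escaped += w
                    break

                lab2 = labels[jx, jy, jz]
                n1 = nn[lab]
                n2 = nn[lab2]
                if n1 != n2:
                    if axis == 0:
                        dn = ux
                    elif axis == 1:
                        dn = uy
                    else:
                        dn = uz
                    ci = abs(dn)
                    ratio = n1 / n2
                    sin2t = ratio * ratio * (1.0 - ci * ci)
                    reflect = False
                    if sin2t >= 1.0:
                        reflect = True  # total internal reflection
                    else:
                        ct2 = math.sqrt(1.0 - sin2t)
                        rs = (n1 * ci - n2 * ct2) / (n1 * ci + n2 * ct2)
                        rp = (n1 * ct2 - n2 * ci) / (n1 * ct2 + n2 * ci)
                        refl_prob = 0.5 * (rs * rs + rp * rp)
                        s, u = _rng_next(s)
                        if u < refl_prob:
                            reflect = True
                    if reflect:
                        if axis == 0:
                            ux = -ux
                            rx = -rx
                        elif axis == 1:
                            uy = -uy
                            ry = -ry
                        else:
                            uz = -uz
                            rz = -rz
                        continue  # stays in the current voxel
                    # refract: scale tangential components, set normal cosine
                    sgn = 1.0 if dn > 0.0 else -1.0
                    if axis == 0:
                        uy *= ratio
                        uz *= ratio
                        ux = sgn * ct2
                    elif axis == 1:
                        ux *= ratio
                        uz *= ratio
                        uy = sgn * ct2
                    else:
                        ux *= ratio
                        uy *= ratio
                        uz = sgn * ct2
                    norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                    ux /= norm
                    uy /= norm
                    uz /= norm
                    rx = 1.0 / ux if (ux > 1e-12 or ux < -1e-12) else big
                    ry = 1.0 / uy if (uy > 1e-12 or uy < -1e-12) else big
                    rz = 1.0 / uz if (uz > 1e-12 or uz < -1e-12) else big
                ix, iy, iz = jx, jy, jz

    return absorbed, escaped, roulette_net, residual
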