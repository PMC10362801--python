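"""Numba photon-transport kernel for a homogeneous voxelized slab.

Single-threaded, with an inline xorshift64* generator seeded per run so a
fixed seed gives a bit-identical fluence grid.  Scoring uses
the absorption-weight estimator: at every interaction site a fraction
``mu_a/mu_t`` of the photon weight is deposited in the enclosing voxel and
the fluence Green's function is recovered as ``deposited / (N mu_a V)``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

C_MM_PER_NS = 299.792458  # vacuum speed of light

# Termination channel indices in the weight tally vector.
TALLY_ESCAPED_TOP = 0
TALLY_ESCAPED_OTHER = 1
TALLY_ABSORBED = 2
TALLY_EXPIRED = 3
TALLY_ROULETTE = 4

_ROULETTE_THRESHOLD = 1e-4
_ROULETTE_SURVIVAL = 10.0


@njit(cache=True, fastmath=True, inline="always")
def _rand(state):
    """xorshift64* uniform in [0, 1); state is a length-1 uint64 array."""
    x = state[0]
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x ^= x >> np.uint64(27)
    state[0] = x
    return float(
        (x * np.uint64(0x2545F4914F6CDD1D)) >> np.uint64(11)
    ) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def _seed_state(seed):
    """SplitMix64 scrambling so small integer seeds give good streams."""
    z = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    if z == 0:
        z = np.uint64(0x9E3779B97F4A7C15)
    state = np.empty(1, dtype=np.uint64)
    state[0] = z
    return state


@njit(cache=True, fastmath=True)
def _fresnel_r(cos_i, n_in, n_out):
    """Unpolarized Fresnel reflectance for internal incidence angle."""
    sin_i2 = 1.0 - cos_i * cos_i
    ratio = n_in / n_out
    sin_t2 = ratio * ratio * sin_i2
    if sin_t2 >= 1.0:
        return 1.0  # total internal reflection
    cos_t = np.sqrt(1.0 - sin_t2)
    rs = (n_in * cos_i - n_out * cos_t) / (n_in * cos_i + n_out * cos_t)
    rp = (n_in * cos_t - n_out * cos_i) / (n_in * cos_t + n_out * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, fastmath=True, inline="always")
def _scatter(ux, uy, uz, g, state):
    """Sample a Henyey-Greenstein deflection and rotate the direction."""
    if abs(g) > 1e-6:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * _rand(state))
        cost = (1.0 + g * g - tmp * tmp) / (2.0 * g)
        if cost > 1.0:
            cost = 1.0
        elif cost < -1.0:
            cost = -1.0
    else:
        cost = 2.0 * _rand(state) - 1.0
    sint = np.sqrt(1.0 - cost * cost)
    # azimuth by rejection sampling of a point in the unit disk (avoids
    # evaluating sin/cos)
    while True:
        a = 2.0 * _rand(state) - 1.0
        b = 2.0 * _rand(state) - 1.0
        r2 = a * a + b * b
        if 0.0 < r2 < 1.0:
            break
    inv = 1.0 / r2
    cosp = (a * a - b * b) * inv
    sinp = 2.0 * a * b * inv
    if abs(uz) > 0.99999:
        nux = sint * cosp
        nuy = sint * sinp
        nuz = cost * (1.0 if uz >= 0.0 else -1.0)
    else:
        denom = np.sqrt(1.0 - uz * uz)
        nux = sint * (ux * uz * cosp - uy * sinp) / denom + ux * cost
        nuy = sint * (uy * uz * cosp + ux * sinp) / denom + uy * cost
        nuz = -sint * cosp * denom + uz * cost
    norm = np.sqrt(nux * nux + nuy * nuy + nuz * nuz)
    return nux / norm, nuy / norm, nuz / norm


@njit(cache=True, fastmath=True)
def run_mc(
    deposit,
    tally,
    n_photons,
    seed,
    mu_a,
    mu_s,
    g,
    n_in,
    n_out,
    ex,
    ey,
    ez,
    voxel,
    x0,
    y0,
    beam_is_cone,
    na,
    n_gates,
    t_end_ns,
):
    """Trace ``n_photons`` and accumulate time-gated absorbed weight.

    ``deposit`` has shape (n_gates, nx, ny, nz) and receives raw absorbed
    weight (not yet normalized).  ``tally`` is a length-5 float64 vector of
    terminal weights per channel (see TALLY_* constants).
    """
    state = _seed_state(seed)
    mu_t = mu_a + mu_s
    inv_c = n_in / C_MM_PER_NS  # ns per mm of path
    gate_w = t_end_ns / n_gates
    hx = 0.5 * ex
    hy = 0.5 * ey
    nx = deposit.shape[1]
    ny = deposit.shape[2]
    nz = deposit.shape[3]
    absorb_frac = mu_a / mu_t

    if beam_is_cone:
        cos_max = np.sqrt(max(0.0, 1.0 - (na / n_out) ** 2))
    else:
        cos_max = 1.0

    for _ in range(n_photons):
        # --- launch ---
        x = x0
        y = y0
        z = 0.0
        if beam_is_cone:
            # Uniform in solid angle within the exterior acceptance cone,
            # then refracted into the medium (fiber NA convention).
            cos_ext = cos_max + (1.0 - cos_max) * _rand(state)
            sin_ext = np.sqrt(1.0 - cos_ext * cos_ext)
            sin_int = sin_ext * n_out / n_in
            cos_int = np.sqrt(1.0 - sin_int * sin_int)
            phi = 2.0 * np.pi * _rand(state)
            ux = sin_int * np.cos(phi)
            uy = sin_int * np.sin(phi)
            uz = cos_int
        else:
            ux = 0.0
            uy = 0.0
            uz = 1.0
        w = 1.0
        t = 0.0
        alive = True

        while alive:
            s = -np.log(1.0 - _rand(state)) / mu_t
            # fast path: the step cannot reach any face from here
            d_safe = hx - abs(x)
            dyy = hy - abs(y)
            if dyy < d_safe:
                d_safe = dyy
            if z < d_safe:
                d_safe = z
            if ez - z < d_safe:
                d_safe = ez - z
            if s < d_safe:
                x += s * ux
                y += s * uy
                z += s * uz
                t += s * inv_c
                s = 0.0
            # --- propagate s, handling boundaries ---
            while s > 0.0:
                # distance to each face along the direction of travel
                if ux > 0.0:
                    dx = (hx - x) / ux
                elif ux < 0.0:
                    dx = (-hx - x) / ux
                else:
                    dx = 1e30
                if uy > 0.0:
                    dy = (hy - y) / uy
                elif uy < 0.0:
                    dy = (-hy - y) / uy
                else:
                    dy = 1e30
                if uz > 0.0:
                    dz = (ez - z) / uz
                elif uz < 0.0:
                    dz = -z / uz
                else:
                    dz = 1e30
                db = dx
                face = 0
                if dy < db:
                    db = dy
                    face = 1
                if dz < db:
                    db = dz
                    face = 2
                if s < db:
                    x += s * ux
                    y += s * uy
                    z += s * uz
                    t += s * inv_c
                    s = 0.0
                else:
                    x += db * ux
                    y += db * uy
                    z += db * uz
                    t += db * inv_c
                    s -= db
                    if face == 2 and uz < 0.0:
                        # top face: Fresnel reflect or escape
                        z = 0.0
                        r = _fresnel_r(-uz, n_in, n_out)
                        if _rand(state) < r:
                            uz = -uz
                        else:
                            tally[TALLY_ESCAPED_TOP] += w
                            alive = False
                            break
                    else:
                        # five absorbing faces
                        tally[TALLY_ESCAPED_OTHER] += w
                        alive = False
                        break
            if not alive:
                break
            if t >= t_end_ns:
                tally[TALLY_EXPIRED] += w
                break
            # --- interaction: deposit and scatter ---
            gate = int(t / gate_w)
            if gate >= n_gates:
                gate = n_gates - 1
            ix = int((x + hx) / voxel)
            iy = int((y + hy) / voxel)
            iz = int(z / voxel)
            if ix < 0:
                ix = 0
            elif ix >= nx:
                ix = nx - 1
            if iy < 0:
                iy = 0
            elif iy >= ny:
                iy = ny - 1
            if iz < 0:
                iz = 0
            elif iz >= nz:
                iz = nz - 1
            dep = w * absorb_frac
            deposit[gate, ix, iy, iz] += dep
            tally[TALLY_ABSORBED] += dep
            w -= dep
            if w < _ROULETTE_THRESHOLD:
                if _rand(state) < 1.0 / _ROULETTE_SURVIVAL:
                    w *= _ROULETTE_SURVIVAL
                else:
                    tally[TALLY_ROULETTE] += w
                    break
            ux, uy, uz = _scatter(ux, uy, uz, g, state)
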