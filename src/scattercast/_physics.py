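"""Low-level photon interaction sampling and the kernel PRNG.

All functions here are ``numba.njit``-compiled scalar kernels shared by the
batch transport engine (:mod:`scattercast._kernel`) and the Python-facing
samplers in :mod:`scattercast.materials`.

The PRNG is xoroshiro128+ with splitmix64 seeding, carried as a mutable
2-element ``uint64`` array so state can be threaded through njit call chains.
"""

from __future__ import annotations

import numpy as np
from numba import njit

ELECTRON_REST_KEV = 511.0  # m_e c^2 in keV (rounded, as in standard kV dosimetry practice)
PHOTON_CUTOFF_KEV = 10.0


# ---------------------------------------------------------------------------
# PRNG: splitmix64 seeding + xoroshiro128+
# ---------------------------------------------------------------------------

@njit(cache=True)
def _splitmix64(x):
    x = np.uint64(x + np.uint64(0x9E3779B97F4A7C15))
    z = x
    z = np.uint64((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9))
    z = np.uint64((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB))
    return x, np.uint64(z ^ (z >> np.uint64(31)))


@njit(cache=True)
def rng_init(seed):
    """Return a fresh xoroshiro128+ state array from an integer seed."""
    state = np.empty(2, dtype=np.uint64)
    x = np.uint64(seed)
    x, s0 = _splitmix64(x)
    x, s1 = _splitmix64(x)
    if s0 == np.uint64(0) and s1 == np.uint64(0):
        s0 = np.uint64(0x853C49E6748FEA9B)
    state[0] = s0
    state[1] = s1
    return state


@njit(cache=True)
def _rotl(x, k):
    return np.uint64((x << np.uint64(k)) | (x >> np.uint64(64 - k)))


@njit(cache=True)
def rng_next_u64(state):
    s0 = state[0]
    s1 = state[1]
    result = np.uint64(s0 + s1)
    s1 = np.uint64(s1 ^ s0)
    state[0] = np.uint64(_rotl(s0, 55) ^ s1 ^ np.uint64(s1 << np.uint64(14)))
    state[1] = _rotl(s1, 36)
    return result


@njit(cache=True)
def rng_uniform(state):
    """Uniform double in [0, 1) with 53-bit resolution."""
    return float(rng_next_u64(state) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


# ---------------------------------------------------------------------------
# Compton (free-electron Klein-Nishina) sampling
# ---------------------------------------------------------------------------

@njit(cache=True)
def compton_scattered_energy(energy_kev, cos_theta):
    """Compton kinematics: E' = E / (1 + (E/m_e c^2)(1 - cos theta))."""
    return energy_kev / (1.0 + (energy_kev / ELECTRON_REST_KEV) * (1.0 - cos_theta))


@njit(cache=True)
def sample_compton(energy_kev, state):
    """Sample (scattered_energy, cos_theta) from the Klein-Nishina DCS.

    Composition-rejection sampling of eps = E'/E on [eps0, 1] from the
    mixture a1 * (1/eps) + a2 * eps, accepted with the angular factor
    1 - eps sin^2(theta) / (1 + eps^2).  This is the standard scheme used
    by general-purpose photon transport codes.
    """
    alpha = energy_kev / ELECTRON_REST_KEV
    eps0 = 1.0 / (1.0 + 2.0 * alpha)
    a1 = -np.log(eps0)
    a2 = 0.5 * (1.0 - eps0 * eps0)
    while True:
        if rng_uniform(state) * (a1 + a2) < a1:
            eps = np.exp(-a1 * rng_uniform(state))
        else:
            eps = np.sqrt(eps0 * eps0 + (1.0 - eps0 * eps0) * rng_uniform(state))
        t = (1.0 - eps) / (alpha * eps)
        sin_theta_sq = t * (2.0 - t)
        greject = 1.0 - eps * sin_theta_sq / (1.0 + eps * eps)
        if rng_uniform(state) <= greject:
            cos_theta = 1.0 - t
            return energy_kev * eps, cos_theta


@njit(cache=True)
def sample_thomson_cos_theta(state):
    """Sample cos(theta) from the Thomson angular law p(mu) ~ 1 + mu^2.

    CDF inversion leads to the depressed cubic mu^3 + 3 mu = 4(2u - 1),
    solved in closed form (single real root).
    """
    b = 4.0 * (2.0 * rng_uniform(state) - 1.0)
    half_b = 0.5 * b
    disc = np.sqrt(half_b * half_b + 1.0)
    mu = np.cbrt(half_b + disc) + np.cbrt(half_b - disc)
    if mu > 1.0:
        mu = 1.0
    elif mu < -1.0:
        mu = -1.0
    return mu


@njit(cache=True)
def rotate_direction(ux, uy, uz, cos_theta, phi):
    """Rotate unit vector u by polar angle theta (cos given) and azimuth phi
    about itself, returning the new unit direction."""
    sin_theta = np.sqrt(max(0.0, 1.0 - cos_theta * cos_theta))
    cos_phi = np.cos(phi)
    sin_phi = np.sin(phi)
    # Build an orthonormal frame around u.
    if abs(uz) < 0.99999:
        # e1 = u x z-hat (normalized)
        norm = np.sqrt(ux * ux + uy * uy)
        e1x = uy / norm
        e1y = -ux / norm
        e1z = 0.0
    else:
        e1x = 1.0
        e1y = 0.0
        e1z = 0.0
    # e2 = u x e1
    e2x = uy * e1z - uz * e1y
    e2y = uz * e1x - ux * e1z
    e2z = ux * e1y - uy * e1x
    nx = sin_theta * (cos_phi * e1x + sin_phi * e2x) + cos_theta * ux
    ny = sin_theta * (cos_phi * e1y + sin_phi * e2y) + cos_theta * uy
    nz = sin_theta * (cos_phi * e1z + sin_phi * e2z) + cos_theta * uz
    # Renormalize to curb drift over long histories.
    inv = 1.0 / np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx * inv, ny * inv, nz * inv


def klein_nishina_pdf(energy_kev, cos_theta):
    """Normalized Klein-Nishina PDF in cos(theta) (vectorized, pure numpy).

    Used as the quadrature reference for sampler tests; normalized
    numerically on a fine grid so it stays independent of the sampler.
    """
    cos_theta = np.asarray(cos_theta, dtype=float)
    alpha = energy_kev / ELECTRON_REST_KEV
    eps = 1.0 / (1.0 + alpha * (1.0 - cos_theta))
    dcs = eps * eps * (eps + 1.0 / eps - (1.0 - cos_theta * cos_theta))
    grid = np.linspace(-1.0, 1.0, 20001)
    eps_g = 1.0 / (1.0 + alpha * (1.0 - grid))
    dcs_g = eps_g * eps_g * (eps_g + 1.0 / eps_g - (1.0 - grid * grid))
    norm = np.trapezoid(dcs_g, grid)
    return dcs / norm
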