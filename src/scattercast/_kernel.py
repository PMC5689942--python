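"""Batch photon transport kernel (numba-compiled).

One compiled routine implements Woodcock (delta) tracking of a photon batch
through the prioritized solid list of a scene, with:

* local (kerma) energy deposition for photoelectric, Compton and sub-cutoff
  terminations;
* outward phase-space-box crossing detection per flight segment (recording
  and/or kill-on-crossing for phase-space replay);
* perfect-absorber solids (photon terminates at the entry point; used for
  the image-intensifier block);
* an optional voxel scoring grid (commissioning profiles);
* per-photon tallies (deposit inside a designated target solid, real
  interaction count) used by calibration and the validation oracles.

Single RNG stream (xoroshiro128+), photons processed sequentially: runs are
bitwise reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._physics import (
    PHOTON_CUTOFF_KEV,
    rng_init,
    rng_uniform,
    rotate_direction,
    sample_compton,
    sample_thomson_cos_theta,
)

_EPS = 1e-9
_BIG = 1e30

KIND_ELLCYL = 0
KIND_BOX = 1


@njit(cache=True)
def _interp(table, e, e_min, e_step):
    idx = (e - e_min) / e_step
    if idx <= 0.0:
        return table[0]
    n = table.shape[0]
    i0 = int(idx)
    if i0 >= n - 1:
        return table[n - 1]
    f = idx - i0
    return table[i0] + (table[i0 + 1] - table[i0]) * f


@njit(cache=True)
def _locate(x, y, z, n_sol, sol_kind, sol_center, sol_rot, sol_params, sol_mat):
    """Index of the first (highest-priority) solid containing the point, or -1."""
    for s in range(n_sol):
        if sol_mat[s] < 0:
            continue  # perfect absorbers handled geometrically, photons never inside
        dx = x - sol_center[s, 0]
        dy = y - sol_center[s, 1]
        dz = z - sol_center[s, 2]
        lx = sol_rot[s, 0, 0] * dx + sol_rot[s, 0, 1] * dy + sol_rot[s, 0, 2] * dz
        ly = sol_rot[s, 1, 0] * dx + sol_rot[s, 1, 1] * dy + sol_rot[s, 1, 2] * dz
        lz = sol_rot[s, 2, 0] * dx + sol_rot[s, 2, 1] * dy + sol_rot[s, 2, 2] * dz
        if sol_kind[s] == KIND_ELLCYL:
            a = sol_params[s, 0]
            b = sol_params[s, 1]
            h = sol_params[s, 2]
            if abs(lz) <= h and (lx / a) ** 2 + (ly / b) ** 2 <= 1.0:
                return s
        else:
            if abs(lx) <= sol_params[s, 0] and abs(ly) <= sol_params[s, 1] \
                    and abs(lz) <= sol_params[s, 2]:
                return s
    return -1


@njit(cache=True)
def _box_entry(x, y, z, ux, uy, uz, cx, cy, cz, rot, hx, hy, hz):
    """Entry distance of a ray into an oriented box; _BIG if missed.
    Returns 0 for interior origins."""
    dx = x - cx
    dy = y - cy
    dz = z - cz
    ox = rot[0, 0] * dx + rot[0, 1] * dy + rot[0, 2] * dz
    oy = rot[1, 0] * dx + rot[1, 1] * dy + rot[1, 2] * dz
    oz = rot[2, 0] * dx + rot[2, 1] * dy + rot[2, 2] * dz
    vx = rot[0, 0] * ux + rot[0, 1] * uy + rot[0, 2] * uz
    vy = rot[1, 0] * ux + rot[1, 1] * uy + rot[1, 2] * uz
    vz = rot[2, 0] * ux + rot[2, 1] * uy + rot[2, 2] * uz
    tmin = -_BIG
    tmax = _BIG
    for k in range(3):
        if k == 0:
            o, v, h = ox, vx, hx
        elif k == 1:
            o, v, h = oy, vy, hy
        else:
            o, v, h = oz, vz, hz
        if abs(v) < 1e-300:
            if abs(o) > h:
                return _BIG
        else:
            t1 = (-h - o) / v
            t2 = (h - o) / v
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
    if tmax <= tmin or tmax <= _EPS:
        return _BIG
    if tmin < 0.0:
        return 0.0
    return tmin


@njit(cache=True)
def _ellcyl_entry(x, y, z, ux, uy, uz, cx, cy, cz, rot, a, b, h):
    """Entry distance of a ray into an elliptic cylinder (lateral surface and
    caps); _BIG if missed, 0 for interior origins."""
    dx = x - cx
    dy = y - cy
    dz = z - cz
    ox = rot[0, 0] * dx + rot[0, 1] * dy + rot[0, 2] * dz
    oy = rot[1, 0] * dx + rot[1, 1] * dy + rot[1, 2] * dz
    oz = rot[2, 0] * dx + rot[2, 1] * dy + rot[2, 2] * dz
    vx = rot[0, 0] * ux + rot[0, 1] * uy + rot[0, 2] * uz
    vy = rot[1, 0] * ux + rot[1, 1] * uy + rot[1, 2] * uz
    vz = rot[2, 0] * ux + rot[2, 1] * uy + rot[2, 2] * uz
    if abs(oz) <= h and (ox / a) ** 2 + (oy / b) ** 2 <= 1.0:
        return 0.0
    best = _BIG
    qa = (vx / a) ** 2 + (vy / b) ** 2
    qb = ox * vx / (a * a) + oy * vy / (b * b)
    qc = (ox / a) ** 2 + (oy / b) ** 2 - 1.0
    disc = qb * qb - qa * qc
    if qa > 0.0 and disc > 0.0:
        sq = np.sqrt(disc)
        for sign in (-1.0, 1.0):
            t = (-qb + sign * sq) / qa
            if _EPS < t < best and abs(oz + t * vz) <= h:
                best = t
    if abs(vz) > 1e-300:
        for zc in (-h, h):
            t = (zc - oz) / vz
            if _EPS < t < best:
                px = ox + t * vx
                py = oy + t * vy
                if (px / a) ** 2 + (py / b) ** 2 <= 1.0:
                    best = t
    return best


@njit(cache=True)
def _aabb_exit(x, y, z, ux, uy, uz, lox, loy, loz, hix, hiy, hiz):
    """(t_entry, t_exit) of a ray against an axis-aligned box (may be negative)."""
    tmin = -_BIG
    tmax = _BIG
    for k in range(3):
        if k == 0:
            o, v, lo, hi = x, ux, lox, hix
        elif k == 1:
            o, v, lo, hi = y, uy, loy, hiy
        else:
            o, v, lo, hi = z, uz, loz, hiz
        if abs(v) < 1e-300:
            if o < lo or o > hi:
                return _BIG, -_BIG
        else:
            t1 = (lo - o) / v
            t2 = (hi - o) / v
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
    return tmin, tmax


@njit(cache=True)
def _grid_track_score(grid_dep, glox, gloy, gloz, gsx, gsy, gsz, gnx, gny, gnz,
                      x, y, z, ux, uy, uz, seg, e, w,
                      n_sol, sol_kind, sol_center, sol_rot, sol_params, sol_mat,
                      mu, ambient_mat, e_min, e_step):
    """Track-length kerma estimator: for the part of the flight segment that
    crosses the scoring grid, add w * E * mu_absorption(material) * dl to
    every traversed voxel."""
    t0, t1 = _aabb_exit(x, y, z, ux, uy, uz, glox, gloy, gloz,
                        glox + gnx * gsx, gloy + gny * gsy, gloz + gnz * gsz)
    if t0 > t1:
        return
    if t0 < 0.0:
        t0 = 0.0
    if t1 > seg:
        t1 = seg
    if t1 <= t0:
        return
    t = t0 + 1e-12
    while t < t1:
        px = x + t * ux
        py = y + t * uy
        pz = z + t * uz
        ix = int((px - glox) / gsx)
        iy = int((py - gloy) / gsy)
        iz = int((pz - gloz) / gsz)
        if ix < 0 or ix >= gnx or iy < 0 or iy >= gny or iz < 0 or iz >= gnz:
            break
        # distance to the next voxel face along the ray
        t_next = t1
        if ux > 0.0:
            tv = (glox + (ix + 1) * gsx - x) / ux
            if tv < t_next:
                t_next = tv
        elif ux < 0.0:
            tv = (glox + ix * gsx - x) / ux
            if tv < t_next:
                t_next = tv
        if uy > 0.0:
            tv = (gloy + (iy + 1) * gsy - y) / uy
            if tv < t_next:
                t_next = tv
        elif uy < 0.0:
            tv = (gloy + iy * gsy - y) / uy
            if tv < t_next:
                t_next = tv
        if uz > 0.0:
            tv = (gloz + (iz + 1) * gsz - z) / uz
            if tv < t_next:
                t_next = tv
        elif uz < 0.0:
            tv = (gloz + iz * gsz - z) / uz
            if tv < t_next:
                t_next = tv
        if t_next <= t:
            t_next = t + 1e-9
        tm = 0.5 * (t + t_next)
        reg = _locate(x + tm * ux, y + tm * uy, z + tm * uz,
                      n_sol, sol_kind, sol_center, sol_rot, sol_params, sol_mat)
        m = sol_mat[reg] if reg >= 0 else ambient_mat
        mu_ab = _interp(mu[m, 4], e, e_min, e_step)
        grid_dep[(ix * gny + iy) * gnz + iz] += w * e * mu_ab * (t_next - t)
        t = t_next + 1e-12


@njit(cache=True)
def transport_batch(
    # photon state (input; not mutated)
    p_pos, p_dir, p_en, p_wt,
    # solids
    sol_kind, sol_center, sol_rot, sol_params, sol_mat,
    world_half,
    # material lookup: mu[m, 4, ne] linear coeffs (pe, incoh, coh, total); majorant[ne]
    mu, mu_maj, e_min, e_step, ambient_mat,
    # phase-space boxes
    box_lo, box_hi, box_tag,
    record_crossings, kill_on_crossing,
    # record output buffers
    rec_pos, rec_dir, rec_en, rec_wt, rec_tag, rec_meta,
    # tallies
    dep_region, cut_region, ledger,  # ledger: [emitted, escaped, discarded, n_discarded]
    target_idx, ph_target_dep, ph_ninter,
    # scoring grid
    use_grid, grid_lo, grid_step, grid_dims, grid_dep,
    seed,
):
    n = p_en.shape[0]
    n_sol = sol_kind.shape[0]
    n_box = box_tag.shape[0]
    state = rng_init(seed)
    rec_cap = rec_en.shape[0]
    glox, gloy, gloz = grid_lo[0], grid_lo[1], grid_lo[2]
    gsx, gsy, gsz = grid_step[0], grid_step[1], grid_step[2]
    gnx, gny, gnz = grid_dims[0], grid_dims[1], grid_dims[2]
    whx, why, whz = world_half[0], world_half[1], world_half[2]

    for i in range(n):
        x = p_pos[i, 0]
        y = p_pos[i, 1]
        z = p_pos[i, 2]
        ux = p_dir[i, 0]
        uy = p_dir[i, 1]
        uz = p_dir[i, 2]
        e = p_en[i]
        w = p_wt[i]
        ledger[0] += e * w
        ph_target_dep[i] = 0.0
        ph_ninter[i] = 0

        if e < PHOTON_CUTOFF_KEV:
            reg = _locate(x, y, z, n_sol, sol_kind, sol_center, sol_rot, sol_params, sol_mat)
            ridx = reg if reg >= 0 else n_sol
            cut_region[ridx] += e * w
            if reg == target_idx:
                ph_target_dep[i] += e * w
            continue

        alive = True
        while alive:
            if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)
                    and np.isfinite(e) and e > 0.0):
                ledger[2] += e * w if np.isfinite(e) else 0.0
                ledger[3] += 1.0
                break
            m_maj = _interp(mu_maj, e, e_min, e_step)
            if m_maj > 0.0:
                s = -np.log(1.0 - rng_uniform(state)) / m_maj
            else:
                s = _BIG

            # distance to world exit (photon is inside the world box)
            t_world = _BIG
            if ux > 0.0:
                t_world = (whx - x) / ux
            elif ux < 0.0:
                t_world = (-whx - x) / ux
            if uy > 0.0:
                t = (why - y) / uy
                if t < t_world:
                    t_world = t
            elif uy < 0.0:
                t = (-why - y) / uy
                if t < t_world:
                    t_world = t
            if uz > 0.0:
                t = (whz - z) / uz
                if t < t_world:
                    t_world = t
            elif uz < 0.0:
                t = (-whz - z) / uz
                if t < t_world:
                    t_world = t
            if t_world < 0.0:
                t_world = 0.0

            # nearest perfect-absorber entry
            t_abs = _BIG
            abs_idx = -1
            for sidx in range(n_sol):
                if sol_mat[sidx] >= 0:
                    continue
                if sol_kind[sidx] == KIND_ELLCYL:
                    t = _ellcyl_entry(x, y, z, ux, uy, uz,
                                      sol_center[sidx, 0], sol_center[sidx, 1],
                                      sol_center[sidx, 2], sol_rot[sidx],
                                      sol_params[sidx, 0], sol_params[sidx, 1],
                                      sol_params[sidx, 2])
                else:
                    t = _box_entry(x, y, z, ux, uy, uz,
                                   sol_center[sidx, 0], sol_center[sidx, 1],
                                   sol_center[sidx, 2], sol_rot[sidx], sol_params[sidx, 0],
                                   sol_params[sidx, 1], sol_params[sidx, 2])
                if 0.0 <= t < t_abs:  # t == 0: origin inside, absorb in place
                    t_abs = t
                    abs_idx = sidx

            seg = s
            if t_world < seg:
                seg = t_world
            if t_abs < seg:
                seg = t_abs

            # outward phase-space-box crossings along [0, seg]
            if n_box > 0 and (record_crossings or kill_on_crossing):
                if kill_on_crossing:
                    t_kill = _BIG
                    for b in range(n_box):
                        t0, t1 = _aabb_exit(x, y, z, ux, uy, uz,
                                            box_lo[b, 0], box_lo[b, 1], box_lo[b, 2],
                                            box_hi[b, 0], box_hi[b, 1], box_hi[b, 2])
                        if t1 > t0 and _EPS < t1 <= seg and t1 < t_kill:
                            t_kill = t1
                    if t_kill <= seg:
                        ledger[1] += e * w
                        break
                else:
                    for b in range(n_box):
                        t0, t1 = _aabb_exit(x, y, z, ux, uy, uz,
                                            box_lo[b, 0], box_lo[b, 1], box_lo[b, 2],
                                            box_hi[b, 0], box_hi[b, 1], box_hi[b, 2])
                        if t1 > t0 and _EPS < t1 <= seg:
                            k = rec_meta[0]
                            if k < rec_cap:
                                rec_pos[k, 0] = x + t1 * ux
                                rec_pos[k, 1] = y + t1 * uy
                                rec_pos[k, 2] = z + t1 * uz
                                rec_dir[k, 0] = ux
                                rec_dir[k, 1] = uy
                                rec_dir[k, 2] = uz
                                rec_en[k] = e
                                rec_wt[k] = w
                                rec_tag[k] = box_tag[b]
                                rec_meta[0] = k + 1
                            else:
                                rec_meta[1] = 1

            if use_grid and seg > 0.0:
                _grid_track_score(grid_dep, glox, gloy, gloz, gsx, gsy, gsz,
                                  gnx, gny, gnz, x, y, z, ux, uy, uz, seg, e, w,
                                  n_sol, sol_kind, sol_center, sol_rot, sol_params,
                                  sol_mat, mu, ambient_mat, e_min, e_step)

            if t_abs <= seg and abs_idx >= 0 and t_abs < _BIG:
                x += t_abs * ux
                y += t_abs * uy
                z += t_abs * uz
                dep_region[abs_idx] += e * w
                if abs_idx == target_idx:
                    ph_target_dep[i] += e * w
                break

            if s >= t_world:
                ledger[1] += e * w
                break

            x += s * ux
            y += s * uy
            z += s * uz
            reg = _locate(x, y, z, n_sol, sol_kind, sol_center, sol_rot, sol_params, sol_mat)
            m = sol_mat[reg] if reg >= 0 else ambient_mat
            mu_tot = _interp(mu[m, 3], e, e_min, e_step)
            if rng_uniform(state) * m_maj > mu_tot:
                continue  # fictitious collision

            ph_ninter[i] += 1
            ridx = reg if reg >= 0 else n_sol
            u2 = rng_uniform(state) * mu_tot
            mu_pe = _interp(mu[m, 0], e, e_min, e_step)
            if u2 < mu_pe:
                dep_region[ridx] += e * w
                if reg == target_idx:
                    ph_target_dep[i] += e * w
                break
            phi = 2.0 * np.pi * rng_uniform(state)
            mu_inc = _interp(mu[m, 1], e, e_min, e_step)
            if u2 < mu_pe + mu_inc:
                e_new, cos_t = sample_compton(e, state)
                dep = (e - e_new) * w
                dep_region[ridx] += dep
                if reg == target_idx:
                    ph_target_dep[i] += dep
                ux, uy, uz = rotate_direction(ux, uy, uz, cos_t, phi)
                e = e_new
                if e < PHOTON_CUTOFF_KEV:
                    cut_region[ridx] += e * w
                    if reg == target_idx:
                        ph_target_dep[i] += e * w
                    break
            else:
                cos_t = sample_thomson_cos_theta(state)
                ux, uy, uz = rotate_direction(ux, uy, uz, cos_t, phi)
    return 0


@njit(cache=True)
def compton_batch(energy_kev, n, seed):
    state = rng_init(seed)
    energies = np.empty(n)
    cosines = np.empty(n)
    for i in range(n):
        e, c = sample_compton(energy_kev, state)
        energies[i] = e
        cosines[i] = c
    return energies, cosines


@njit(cache=True)
def thomson_batch(n, seed):
    state = rng_init(seed)
    out = np.empty(n)
    for i in range(n):
        out[i] = sample_thomson_cos_theta(state)
    return out
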