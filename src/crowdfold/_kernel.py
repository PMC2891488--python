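"""Numba-compiled inner loop of the Langevin integrator.

Implements exactly the arithmetic of the reference modules
(:mod:`crowdfold.forces`, :mod:`crowdfold.solvent`) over flat arrays:
spring terms, the linear soft-core steric ramp with contact distance
``r_i + r_j``, backbone hydrogen bonding, boundary restraints,
exposure-gated drag and Poisson solvent kicks with blocked-direction
rejection.  The test suite checks agreement with the reference step to
1e-9 with the stochastic terms disabled.

Randomness uses numba's global legacy RNG, seeded once per chunk by the
caller; given the same chunk seeds the trajectory is bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

ROLE_BACKBONE = 0
ROLE_SIDECHAIN = 1
ROLE_CROWDER = 2
ROLE_RIBOSOME = 3
ROLE_EXIT = 4

# drag stability clamp: the per-step velocity decay factor
# gamma * area * dt / m is never allowed to exceed this value
MAX_DRAG_FACTOR = 0.95

FOUR_PI = 4.0 * np.pi


@njit(cache=False)
def _rebuild_caps(pos, radius, active, n, cutoff,
                  cap_dir, cap_cos, cap_count):
    """Occluding angular caps per particle, sorted nearest-first."""
    dist = np.empty(n)
    order = np.empty(n, dtype=np.int64)
    for i in range(n):
        cap_count[i] = 0
        if not active[i]:
            continue
        m = 0
        for j in range(n):
            if j == i or not active[j] or radius[j] <= 0.0:
                continue
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            # cutoff on the occluder's surface, so large spheres
            # (crowders, ribosome) occlude even with distant centres
            if d == 0.0 or d - radius[j] > cutoff:
                continue
            dist[m] = d
            order[m] = j
            m += 1
        # insertion sort of neighbour list by distance (m is small)
        for a in range(1, m):
            da = dist[a]
            ja = order[a]
            b = a - 1
            while b >= 0 and dist[b] > da:
                dist[b + 1] = dist[b]
                order[b + 1] = order[b]
                b -= 1
            dist[b + 1] = da
            order[b + 1] = ja
        for a in range(m):
            j = order[a]
            d = dist[a]
            rj = radius[j]
            if rj >= d:
                cap_dir[i, a, 0] = 1.0
                cap_dir[i, a, 1] = 0.0
                cap_dir[i, a, 2] = 0.0
                cap_cos[i, a] = -2.0  # engulfed: every direction blocked
            else:
                inv = 1.0 / d
                cap_dir[i, a, 0] = (pos[j, 0] - pos[i, 0]) * inv
                cap_dir[i, a, 1] = (pos[j, 1] - pos[i, 1]) * inv
                cap_dir[i, a, 2] = (pos[j, 2] - pos[i, 2]) * inv
                s = rj * inv
                cap_cos[i, a] = np.sqrt(1.0 - s * s)
        cap_count[i] = m


@njit(cache=False)
def _direction_blocked(i, ux, uy, uz, cap_dir, cap_cos, cap_count):
    for a in range(cap_count[i]):
        dot = (ux * cap_dir[i, a, 0] + uy * cap_dir[i, a, 1]
               + uz * cap_dir[i, a, 2])
        if dot > cap_cos[i, a]:
            return True
    return False


@njit(cache=False)
def _exposure(rays, n, active, cap_dir, cap_cos, cap_count, frac):
    n_rays = rays.shape[0]
    for i in range(n):
        if not active[i]:
            frac[i] = 0.0
            continue
        if cap_count[i] == 0:
            frac[i] = 1.0
            continue
        blocked = 0
        for r in range(n_rays):
            if _direction_blocked(i, rays[r, 0], rays[r, 1], rays[r, 2],
                                  cap_dir, cap_cos, cap_count):
                blocked += 1
        frac[i] = 1.0 - blocked / n_rays


@njit(cache=False)
def run_chunk(pos, vel, mass, radius, vdw_r, role, hydrophobic, movable,
              active,
              sp_i, sp_j, sp_k, sp_L0, sp_active,
              excl,
              bb_idx, n_bb, hb_threshold, hb_strength, hb_min_sep, hb_half,
              container_center, container_radius, rib_center, rib_radius,
              k_boundary, k_tether, exit_idx,
              gamma, kick_speed, kick_rate, hmult, dt, speed_cap,
              cutoff, rays, exposure_interval, vdw_max_rep,
              n_steps, step0, seed, frac):
    """Advance the system ``n_steps`` iterations in place.

    Returns (status, bad_particle): status is -1 on success, otherwise
    the step index at which a non-finite coordinate appeared.
    """
    n = pos.shape[0]
    np.random.seed(seed)
    cap_dir = np.zeros((n, n, 3))
    cap_cos = np.zeros((n, n))
    cap_count = np.zeros(n, dtype=np.int64)
    force = np.zeros((n, 3))
    area = np.zeros(n)
    offs = np.zeros((n_bb if n_bb > 0 else 1, 3))

    for t in range(n_steps):
        if t == 0 or (step0 + t) % exposure_interval == 0:
            _rebuild_caps(pos, radius, active, n, cutoff,
                          cap_dir, cap_cos, cap_count)
            _exposure(rays, n, active, cap_dir, cap_cos, cap_count, frac)
            for i in range(n):
                area[i] = frac[i] * FOUR_PI * radius[i] * radius[i]

        for i in range(n):
            force[i, 0] = 0.0
            force[i, 1] = 0.0
            force[i, 2] = 0.0

        # springs
        for s in range(sp_i.shape[0]):
            if not sp_active[s]:
                continue
            i = sp_i[s]
            j = sp_j[s]
            if not active[i] or not active[j]:
                continue
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d == 0.0:
                continue
            f = sp_k[s] * (d - sp_L0[s]) / d
            force[i, 0] += f * dx
            force[i, 1] += f * dy
            force[i, 2] += f * dz
            force[j, 0] -= f * dx
            force[j, 1] -= f * dy
            force[j, 2] -= f * dz

        # steric repulsion (linear soft-core ramp, contact = r_i + r_j)
        for i in range(n):
            if not active[i] or role[i] == ROLE_RIBOSOME or role[i] == ROLE_EXIT:
                continue
            for j in range(i + 1, n):
                if not active[j] or role[j] == ROLE_RIBOSOME or role[j] == ROLE_EXIT:
                    continue
                if excl[i, j]:
                    continue
                contact = vdw_r[i] + vdw_r[j]
                dx = pos[j, 0] - pos[i, 0]
                dy = pos[j, 1] - pos[i, 1]
                dz = pos[j, 2] - pos[i, 2]
                if abs(dx) > contact or abs(dy) > contact or abs(dz) > contact:
                    continue
                d = np.sqrt(dx * dx + dy * dy + dz * dz)
                if d == 0.0 or d >= contact:
                    continue
                mag = vdw_max_rep[role[i], role[j]] * (1.0 - d / contact) / d
                force[i, 0] -= mag * dx
                force[i, 1] -= mag * dy
                force[i, 2] -= mag * dz
                force[j, 0] += mag * dx
                force[j, 1] += mag * dy
                force[j, 2] += mag * dz

        # backbone hydrogen bonding via virtual bisector sites
        if n_bb >= hb_min_sep + 1 and hb_strength > 0.0:
            for a in range(n_bb):
                offs[a, 0] = 0.0
                offs[a, 1] = 0.0
                offs[a, 2] = 0.0
            for a in range(1, n_bb - 1):
                i = bb_idx[a]
                ux = pos[bb_idx[a - 1], 0] - pos[i, 0]
                uy = pos[bb_idx[a - 1], 1] - pos[i, 1]
                uz = pos[bb_idx[a - 1], 2] - pos[i, 2]
                vx = pos[bb_idx[a + 1], 0] - pos[i, 0]
                vy = pos[bb_idx[a + 1], 1] - pos[i, 1]
                vz = pos[bb_idx[a + 1], 2] - pos[i, 2]
                nu = np.sqrt(ux * ux + uy * uy + uz * uz)
                nv = np.sqrt(vx * vx + vy * vy + vz * vz)
                if nu == 0.0 or nv == 0.0:
                    continue
                bx = ux / nu + vx / nv
                by = uy / nu + vy / nv
                bz = uz / nu + vz / nv
                nb = np.sqrt(bx * bx + by * by + bz * bz)
                if nb < 1e-12:
                    continue
                offs[a, 0] = hb_half * bx / nb
                offs[a, 1] = hb_half * by / nb
                offs[a, 2] = hb_half * bz / nb
            for a in range(n_bb):
                if offs[a, 0] == 0.0 and offs[a, 1] == 0.0 and offs[a, 2] == 0.0:
                    continue
                ia = bb_idx[a]
                for b in range(a + hb_min_sep, n_bb):
                    if offs[b, 0] == 0.0 and offs[b, 1] == 0.0 and offs[b, 2] == 0.0:
                        continue
                    ib = bb_idx[b]
                    best_d = 1e30
                    best_x = 0.0
                    best_y = 0.0
                    best_z = 0.0
                    for sa in range(-1, 2, 2):
                        for sb in range(-1, 2, 2):
                            dx = (pos[ib, 0] + sb * offs[b, 0]
                                  - pos[ia, 0] - sa * offs[a, 0])
                            dy = (pos[ib, 1] + sb * offs[b, 1]
                                  - pos[ia, 1] - sa * offs[a, 1])
                            dz = (pos[ib, 2] + sb * offs[b, 2]
                                  - pos[ia, 2] - sa * offs[a, 2])
                            d = np.sqrt(dx * dx + dy * dy + dz * dz)
                            if d < best_d:
                                best_d = d
                                best_x = dx
                                best_y = dy
                                best_z = dz
                    if 0.0 < best_d < hb_threshold:
                        f = hb_strength / best_d
                        force[ia, 0] += f * best_x
                        force[ia, 1] += f * best_y
                        force[ia, 2] += f * best_z
                        force[ib, 0] -= f * best_x
                        force[ib, 1] -= f * best_y
                        force[ib, 2] -= f * best_z

        # boundary restraints and exit tether
        for i in range(n):
            if not active[i] or role[i] == ROLE_RIBOSOME:
                continue
            r = radius[i]
            if np.isfinite(container_radius):
                dx = pos[i, 0] - container_center[0]
                dy = pos[i, 1] - container_center[1]
                dz = pos[i, 2] - container_center[2]
                d = np.sqrt(dx * dx + dy * dy + dz * dz)
                over = d + r - container_radius
                if over > 0.0 and d > 0.0:
                    f = k_boundary * over / d
                    force[i, 0] -= f * dx
                    force[i, 1] -= f * dy
                    force[i, 2] -= f * dz
            dx = pos[i, 0] - rib_center[0]
            dy = pos[i, 1] - rib_center[1]
            dz = pos[i, 2] - rib_center[2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            pen = rib_radius + r - d
            if pen > 0.0 and d > 0.0:
                f = k_boundary * pen / d
                force[i, 0] += f * dx
                force[i, 1] += f * dy
                force[i, 2] += f * dz
            if i == exit_idx:
                force[i, 0] -= k_tether * (pos[i, 0] - container_center[0])
                force[i, 1] -= k_tether * (pos[i, 1] - container_center[1])
                force[i, 2] -= k_tether * (pos[i, 2] - container_center[2])

        # velocity update: multiplicative exposure-gated drag + forces
        for i in range(n):
            if not active[i] or not movable[i]:
                vel[i, 0] = 0.0
                vel[i, 1] = 0.0
                vel[i, 2] = 0.0
                continue
            fac = gamma * area[i] * dt / mass[i]
            if fac > MAX_DRAG_FACTOR:
                fac = MAX_DRAG_FACTOR
            keep = 1.0 - fac
            scale = dt / mass[i]
            vel[i, 0] = vel[i, 0] * keep + force[i, 0] * scale
            vel[i, 1] = vel[i, 1] * keep + force[i, 1] * scale
            vel[i, 2] = vel[i, 2] * keep + force[i, 2] * scale

        # solvent kicks
        if kick_rate > 0.0:
            for i in range(n):
                if not active[i] or not movable[i]:
                    continue
                lam = kick_rate * area[i]
                if hydrophobic[i] and role[i] == ROLE_SIDECHAIN:
                    lam *= hmult
                if lam <= 0.0:
                    continue
                count = np.random.poisson(lam)
                for _ in range(count):
                    ux = np.random.normal(0.0, 1.0)
                    uy = np.random.normal(0.0, 1.0)
                    uz = np.random.normal(0.0, 1.0)
                    nu = np.sqrt(ux * ux + uy * uy + uz * uz)
                    if nu == 0.0:
                        continue
                    ux /= nu
                    uy /= nu
                    uz /= nu
                    if _direction_blocked(i, ux, uy, uz,
                                          cap_dir, cap_cos, cap_count):
                        continue
                    dv = kick_speed / mass[i]
                    vel[i, 0] -= ux * dv
                    vel[i, 1] -= uy * dv
                    vel[i, 2] -= uz * dv

        # speed cap and position update
        for i in range(n):
            if not active[i] or not movable[i]:
                continue
            sp = np.sqrt(vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
            if sp > speed_cap:
                sc = speed_cap / sp
                vel[i, 0] *= sc
                vel[i, 1] *= sc
                vel[i, 2] *= sc
            pos[i, 0] += vel[i, 0] * dt
            pos[i, 1] += vel[i, 1] * dt
            pos[i, 2] += vel[i, 2] * dt
            if not (np.isfinite(pos[i, 0]) and np.isfinite(pos[i, 1])
                    and np.isfinite(pos[i, 2])):
                return t, i
    return -1, -1
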