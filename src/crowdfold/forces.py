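"""Pairwise force terms of the coarse-grained force field.

The total force on every particle is the sum of spring terms (cov, bb,
sc, plus machinery tethers), a purely repulsive steric term (vdw), a
short-range backbone hydrogen-bond attraction (hb) and the container /
ribosome boundary restraints.  All pairwise terms obey Newton's third
law exactly; the boundary term acts against fixed geometry and does
not.

This module is the plain-numpy reference implementation; the numba
kernel in :mod:`crowdfold._kernel` reproduces the same arithmetic for
production runs and is cross-checked against this module in the test
suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model_core import (ForceFieldParams, ParticleSystem, ProteinChain, Role,
                         Spring, role_name)

logger = logging.getLogger(__name__)

_warned_degenerate = False
_warned_pairs: set[tuple[str, str]] = set()

TERM_NAMES = ("cov", "bb", "sc", "vdw", "hb", "boundary")


@dataclass
class ForceReport:
    """Per-particle forces with an optional per-term breakdown."""

    total: np.ndarray                      # (n, 3)
    terms: Optional[dict[str, np.ndarray]] = None

    def term(self, name: str) -> np.ndarray:
        if self.terms is None:
            raise ValueError("force report carries no breakdown")
        return self.terms[name]


def harmonic_force(x_i: np.ndarray, x_j: np.ndarray, k: float, L0: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Linear spring force pair; restores the distance toward ``L0``.

    Coincident endpoints with a positive rest length have no defined
    direction: the force is zero and a warning is logged once.
    """
    global _warned_degenerate
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    d_vec = x_j - x_i
    d = float(np.linalg.norm(d_vec))
    if d == 0.0:
        if L0 > 0 and not _warned_degenerate:
            logger.warning("coincident spring endpoints with rest length %g; "
                           "returning zero force", L0)
            _warned_degenerate = True
        z = np.zeros(3)
        return z, z.copy()
    f_i = k * (d - L0) * (d_vec / d)
    return f_i, -f_i


def _vdw_lookup(type_i: str, type_j: str, table: dict,
                radii: Optional[dict[str, float]] = None):
    key = tuple(sorted((type_i, type_j)))
    if key in table:
        return table[key]
    if radii is not None and type_i in radii and type_j in radii:
        if key not in _warned_pairs:
            logger.warning("vdw table has no entry for %s; "
                           "falling back to radii-sum rule", key)
            _warned_pairs.add(key)
        return (radii[type_i] + radii[type_j], 1.0)
    raise KeyError(f"vdw table has no entry for pair {key} and no radii fallback")


def vdw_magnitude(d: float, entry) -> float:
    """Repulsion magnitude at distance ``d`` for one table entry.

    An entry is either ``(contact_distance, max_repulsion)`` — a linear
    soft-core ramp from ``max_repulsion`` at d=0 to zero at contact —
    or an (m, 2) array of (distance, magnitude) samples interpreted as
    a piecewise-linear profile (zero beyond its last knot).
    """
    entry_arr = np.asarray(entry, dtype=float)
    if entry_arr.ndim == 1:  # (contact, max_repulsion) ramp
        contact, max_rep = float(entry_arr[0]), float(entry_arr[1])
        if d >= contact or contact <= 0:
            return 0.0
        return max_rep * (1.0 - d / contact)
    xs, ys = entry_arr[:, 0], entry_arr[:, 1]
    if d >= xs[-1]:
        return 0.0
    return float(np.interp(d, xs, ys))


def vdw_force(type_i: str, type_j: str, x_i: np.ndarray, x_j: np.ndarray,
              table: dict, radii: Optional[dict[str, float]] = None
              ) -> tuple[np.ndarray, np.ndarray]:
    """Purely repulsive steric force between two particles."""
    entry = _vdw_lookup(type_i, type_j, table, radii)
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    d_vec = x_j - x_i
    d = float(np.linalg.norm(d_vec))
    if d == 0.0:
        z = np.zeros(3)
        return z, z.copy()
    mag = vdw_magnitude(d, entry)
    f_i = -mag * (d_vec / d)   # pushes i away from j
    return f_i, -f_i


def hb_virtual_offsets(positions: np.ndarray, backbone_idx: np.ndarray,
                       half_length: float) -> np.ndarray:
    """Unit-bisector offsets (scaled) for the virtual H/O sites.

    Site pair of backbone bead i is ``x_i +/- offset_i``; terminal
    residues (no two chain neighbours) get a zero offset and are
    excluded from hydrogen bonding.
    """
    nb = len(backbone_idx)
    offsets = np.zeros((nb, 3))
    for a in range(1, nb - 1):
        xi = positions[backbone_idx[a]]
        u = positions[backbone_idx[a - 1]] - xi
        v = positions[backbone_idx[a + 1]] - xi
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            continue
        b = u / nu + v / nv
        nb_ = np.linalg.norm(b)
        if nb_ < 1e-12:
            continue
        offsets[a] = half_length * b / nb_
    return offsets


def hb_force(chain: ProteinChain, positions: np.ndarray,
             ff: ForceFieldParams, n_particles: Optional[int] = None,
             synthesized: Optional[int] = None) -> np.ndarray:
    """Backbone hydrogen-bond attraction.

    For backbone pairs separated by at least ``hb_min_separation``
    residues whose closest virtual-site pair comes within
    ``hb_threshold``, a constant-magnitude attraction acts along the
    virtual-site axis on both backbone beads.
    """
    n = positions.shape[0] if n_particles is None else n_particles
    out = np.zeros((n, 3))
    nres = len(chain) if synthesized is None else synthesized
    bb = np.asarray(chain.backbone_ids[:nres], dtype=int)
    if len(bb) < ff.hb_min_separation + 1:
        return out
    half = 0.5 * ff.cov_ca_ca
    offsets = hb_virtual_offsets(positions, bb, half)
    for a in range(len(bb)):
        if not np.any(offsets[a]):
            continue
        for b in range(a + ff.hb_min_separation, len(bb)):
            if not np.any(offsets[b]):
                continue
            xi, xj = positions[bb[a]], positions[bb[b]]
            best = None
            for sa in (+1, -1):
                for sb in (+1, -1):
                    si = xi + sa * offsets[a]
                    sj = xj + sb * offsets[b]
                    dv = sj - si
                    d = np.linalg.norm(dv)
                    if best is None or d < best[0]:
                        best = (d, dv)
            d, dv = best
            if d < ff.hb_threshold and d > 0:
                f = ff.hb_strength * dv / d
                out[bb[a]] += f
                out[bb[b]] -= f
    return out


def spring_forces(positions: np.ndarray, springs: Sequence[Spring],
                  active: Optional[np.ndarray] = None,
                  n_particles: Optional[int] = None) -> dict[str, np.ndarray]:
    """Evaluate a spring list, grouped by category."""
    n = positions.shape[0] if n_particles is None else n_particles
    terms: dict[str, np.ndarray] = {}
    for sp in springs:
        if active is not None and not (active[sp.i] and active[sp.j]):
            continue
        f_i, f_j = harmonic_force(positions[sp.i], positions[sp.j],
                                  sp.stiffness, sp.rest_length)
        arr = terms.setdefault(sp.category, np.zeros((n, 3)))
        arr[sp.i] += f_i
        arr[sp.j] += f_j
    return terms


def vdw_forces(system: ParticleSystem, ff: ForceFieldParams,
               exclude_pairs: Optional[set[tuple[int, int]]] = None) -> np.ndarray:
    """Steric repulsion over all active particle pairs.

    Ribosome and exit-point particles do not take part (the ribosome
    excludes through the boundary term; the exit point is a tether
    anchor only), and covalently bonded pairs are skipped.
    """
    n = system.n
    out = np.zeros((n, 3))
    idx = [i for i in range(n)
           if system.active[i] and system.role[i] not in
           (int(Role.RIBOSOME), int(Role.EXIT_POINT))]
    for a in range(len(idx)):
        i = idx[a]
        for b in range(a + 1, len(idx)):
            j = idx[b]
            if exclude_pairs and (i, j) in exclude_pairs:
                continue
            f_i, f_j = vdw_force(role_name(system.role[i]),
                                 role_name(system.role[j]),
                                 system.pos[i], system.pos[j],
                                 ff.vdw_table, ff.vdw_radii)
            out[i] += f_i
            out[j] += f_j
    return out


def boundary_forces(system: ParticleSystem, scene, ff: ForceFieldParams
                    ) -> np.ndarray:
    """Containment sphere, ribosome exclusion and exit-point tether.

    A non-ribosome particle whose surface extends past the container
    feels an inward spring of stiffness ``k_boundary``; a particle
    whose surface penetrates the ribosome sphere feels an outward
    repulsion of the same stiffness; the exit-point particle is tied to
    the container centre by a spring of stiffness ``k_tether``.
    """
    n = system.n
    out = np.zeros((n, 3))
    if scene is None:
        return out
    center = np.asarray(scene.container_center, dtype=float)
    rib_c = np.asarray(scene.ribosome_center, dtype=float)
    for i in range(n):
        if not system.active[i] or system.role[i] == int(Role.RIBOSOME):
            continue
        r = system.solvent_radius[i]
        # container restraint
        if np.isfinite(scene.container_radius):
            d_vec = system.pos[i] - center
            d = np.linalg.norm(d_vec)
            over = d + r - scene.container_radius
            if over > 0 and d > 0:
                out[i] -= ff.k_boundary * over * (d_vec / d)
        # ribosome exclusion
        d_vec = system.pos[i] - rib_c
        d = np.linalg.norm(d_vec)
        pen = scene.ribosome_radius + r - d
        if pen > 0 and d > 0:
            out[i] += ff.k_boundary * pen * (d_vec / d)
        # exit-point tether to container centre
        if system.role[i] == int(Role.EXIT_POINT):
            d_vec = system.pos[i] - center
            out[i] -= ff.k_tether * d_vec
    return out


def total_force(system: ParticleSystem, chain: Optional[ProteinChain],
                scene, ff: ForceFieldParams,
                extra_springs: Sequence[Spring] = (),
                breakdown: bool = True) -> ForceReport:
    """Sum of all force-field terms, with per-term breakdown."""
    n = system.n
    terms = {name: np.zeros((n, 3)) for name in TERM_NAMES}
    if n == 0:
        return ForceReport(total=np.zeros((0, 3)), terms=terms if breakdown else None)

    springs: list[Spring] = list(extra_springs)
    exclude: set[tuple[int, int]] = set()
    if chain is not None:
        springs = list(chain.springs) + springs
        for sp in chain.springs:
            if sp.category == "cov":
                exclude.add((min(sp.i, sp.j), max(sp.i, sp.j)))

    for cat, arr in spring_forces(system.pos, springs, system.active, n).items():
        if cat == "tether":
            terms["boundary"] += arr
        else:
            terms[cat] += arr
    terms["vdw"] += vdw_forces(system, ff, exclude)
    if chain is not None:
        terms["hb"] += hb_force(chain, system.pos, ff, n,
                                synthesized=chain.synthesized_count or None)
    terms["boundary"] += boundary_forces(system, scene, ff)

    total = np.zeros((n, 3))
    for arr in terms.values():
        total += arr
    return ForceReport(total=total, terms=terms if breakdown else None)
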