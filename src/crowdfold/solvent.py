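"""Hybrid implicit-explicit solvent model.

Drag and random solvent kicks act only on the solvent-exposed part of
each particle's surface.  Exposure is estimated by casting a fixed set
of quasi-uniform rays (a Fibonacci sphere) from each particle and
counting the directions not occluded by neighbouring solvent spheres;
the set is fixed, so exposure is deterministic and trajectories are
seed-reproducible.

Kicks arrive in Poisson numbers proportional to the accessible area,
all with the same speed; a kick whose source direction is blocked by
another particle is discarded.  Hydrophobic side-chain beads receive
kicks at an increased rate, which biases them toward burial — the
model's only use of hydrophobicity, and the origin of hydrophobic
collapse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np

from .model_core import LangevinParams, ParticleSystem, Role

__all__ = ["ExposureEstimate", "fibonacci_directions", "exposed_fraction",
           "compute_exposure", "sample_kicks", "drag_force", "drag_forces"]


@lru_cache(maxsize=8)
def fibonacci_directions(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors on the sphere (deterministic)."""
    k = np.arange(n, dtype=float)
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = 2.0 * math.pi * k / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    dirs = np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)
    dirs.setflags(write=False)
    return dirs


@dataclass
class ExposureEstimate:
    """Exposed surface fraction and accessible area per particle."""

    fraction: np.ndarray   # (n,) in [0, 1]
    area: np.ndarray       # (n,) Angstrom^2; fraction * 4 pi r^2


def _occluder_caps(i: int, system: ParticleSystem, cutoff: float):
    """Angular caps (unit direction, cos half-angle) of the neighbours
    that can occlude particle ``i`` within the neighbour cutoff."""
    dirs = []
    cosines = []
    xi = system.pos[i]
    for j in range(system.n):
        if j == i or not system.active[j]:
            continue
        rj = system.solvent_radius[j]
        if rj <= 0:
            continue
        d_vec = system.pos[j] - xi
        d = float(np.linalg.norm(d_vec))
        # cutoff applies to the occluder's surface so that large
        # spheres occlude even when their centres are distant
        if d == 0.0 or d - rj > cutoff:
            continue
        if rj >= d:           # engulfing neighbour blocks everything
            dirs.append(d_vec / d)
            cosines.append(-2.0)  # every dot product exceeds this
            continue
        dirs.append(d_vec / d)
        cosines.append(math.sqrt(1.0 - (rj / d) ** 2))
    if not dirs:
        return np.zeros((0, 3)), np.zeros(0)
    return np.asarray(dirs), np.asarray(cosines)


def _blocked_mask(directions: np.ndarray, cap_dirs: np.ndarray,
                  cap_cos: np.ndarray) -> np.ndarray:
    """True for each direction lying inside any occluding cap.

    A ray from the particle centre along ``u`` intersects a neighbour
    sphere of radius r at distance d exactly when the angle between u
    and the neighbour direction is below asin(r/d), i.e. when
    ``dot(u, d_hat) > cos(asin(r/d))``.
    """
    if cap_dirs.shape[0] == 0:
        return np.zeros(directions.shape[0], dtype=bool)
    dots = directions @ cap_dirs.T               # (n_dirs, n_caps)
    return np.any(dots > cap_cos[None, :], axis=1)


def exposed_fraction(i: int, system: ParticleSystem,
                     lp: LangevinParams) -> float:
    """Fraction of quasi-uniform outward rays from particle ``i`` that
    escape all neighbouring solvent spheres within the cutoff."""
    dirs = fibonacci_directions(lp.exposure_rays)
    cap_dirs, cap_cos = _occluder_caps(i, system, lp.neighbor_cutoff)
    blocked = _blocked_mask(dirs, cap_dirs, cap_cos)
    return 1.0 - float(np.count_nonzero(blocked)) / lp.exposure_rays


def compute_exposure(system: ParticleSystem, lp: LangevinParams
                     ) -> ExposureEstimate:
    """Exposure for every particle (inactive particles get zero)."""
    n = system.n
    fraction = np.zeros(n)
    for i in range(n):
        if system.active[i]:
            fraction[i] = exposed_fraction(i, system, lp)
    area = fraction * 4.0 * math.pi * system.solvent_radius ** 2
    return ExposureEstimate(fraction=fraction, area=area)


def kick_rate_for(i: int, system: ParticleSystem, exposure: ExposureEstimate,
                  lp: LangevinParams) -> float:
    """Poisson mean of the kick count per iteration for particle i."""
    lam = lp.kick_rate * exposure.area[i]
    if system.hydrophobic[i] and system.role[i] == int(Role.SIDECHAIN):
        lam *= lp.hydrophobic_multiplier
    return lam


def sample_kicks(system: ParticleSystem, exposure: ExposureEstimate,
                 lp: LangevinParams, rng: np.random.Generator,
                 counts: Optional[np.ndarray] = None) -> np.ndarray:
    """Velocity increments from solvent kicks for one iteration.

    Per particle the kick count is Poisson with mean
    ``kick_rate * accessible_area`` (times the hydrophobic multiplier
    for hydrophobic side-chain beads).  Each kick's source direction is
    uniform on the sphere; if that direction is blocked by a neighbour
    the kick is discarded.  An accepted kick adds ``kick_speed / mass``
    directed away from the source (impulses enter the equation of
    motion divided by the particle mass).  When ``counts`` (an int
    array of length n) is supplied it is filled with the number of
    accepted kicks per particle.
    """
    n = system.n
    dv = np.zeros((n, 3))
    if lp.kick_rate == 0:
        return dv
    for i in range(n):
        if not system.active[i] or not system.movable[i]:
            continue
        lam = kick_rate_for(i, system, exposure, lp)
        if lam <= 0:
            continue
        count = rng.poisson(lam)
        if count == 0:
            continue
        cap_dirs, cap_cos = _occluder_caps(i, system, lp.neighbor_cutoff)
        for _ in range(count):
            u = rng.standard_normal(3)
            nu = np.linalg.norm(u)
            if nu == 0:
                continue
            u /= nu
            if cap_dirs.shape[0] and bool(
                    np.any(u @ cap_dirs.T > cap_cos)):
                continue  # blocked source direction: kick discarded
            dv[i] -= u * (lp.kick_speed / system.mass[i])
            if counts is not None:
                counts[i] += 1
    return dv


def drag_force(i: int, system: ParticleSystem, exposure: ExposureEstimate,
               lp: LangevinParams) -> np.ndarray:
    """Drag on one particle: ``-gamma * accessible_area * velocity``."""
    return -lp.gamma * exposure.area[i] * system.vel[i]


def drag_forces(system: ParticleSystem, exposure: ExposureEstimate,
                lp: LangevinParams) -> np.ndarray:
    return -lp.gamma * exposure.area[:, None] * system.vel
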