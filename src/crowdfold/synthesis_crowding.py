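"""The simulated cell: ribosome, co-translational synthesis, crowders.

The cell is a containing sphere (default diameter 100 A) holding the
growing protein and a set of inert crowder spheres (default diameter
30 A, mass 150 base units — the excluded volume of a ~75-residue
protein).  A heavy ribosome sphere (radius 100 A) sits outside the
container with its synthesis exit point on its surface; the exit point
is tethered to the container centre so the protein is synthesized into
the middle of the crowded region rather than at the boundary.

Synthesis adds one residue's beads at the exit point every ``rate``
iterations (default 1000); the newest backbone bead is tethered to the
exit point and the previous tether is released, so exactly one tether
exists while synthesis is in progress.

The crowding level is the fraction of the ribosome-free container
volume occupied by crowder spheres; crowders interact through steric
repulsion only and move freely under the same Langevin dynamics as the
protein.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .integrator import CompiledState, run
from .model_core import (ForceFieldParams, LangevinParams, ParticleSystem,
                         ProteinChain, Role, build_chain, default_params)

logger = logging.getLogger(__name__)

__all__ = ["Scene", "close_packing_fraction", "sphere_overlap_volume",
           "available_volume", "crowder_count", "realised_fraction",
           "place_crowders", "SynthesisHook", "build_cell",
           "run_crowding_simulation", "run_crowding_sweep", "sampling_plan"]

CLOSE_PACKING = math.pi / math.sqrt(18.0)   # max sphere packing, ~0.7405


def close_packing_fraction() -> float:
    """Upper bound on the excluded-volume fraction of equal spheres."""
    return CLOSE_PACKING


@dataclass
class Scene:
    """Geometry and contents of the simulated cell."""

    container_radius: float = 50.0
    ribosome_radius: float = 100.0
    container_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    ribosome_center: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, -100.0]))
    exit_particle_id: int = -1
    crowder_radius: float = 15.0
    crowder_mass: float = 150.0
    crowder_ids: list = field(default_factory=list)
    target_fraction: float = 0.0
    # D15: the excluded-volume denominator is the ribosome-free container
    # volume; set to "container" to use the whole container volume.
    volume_denominator: str = "ribosome_free"

    def __post_init__(self) -> None:
        self.container_center = np.asarray(self.container_center, dtype=float)
        self.ribosome_center = np.asarray(self.ribosome_center, dtype=float)
        if np.isfinite(self.container_radius) and \
                self.crowder_radius >= self.container_radius:
            raise ValueError("crowder radius must be below container radius")
        if not (0.0 <= self.target_fraction < CLOSE_PACKING):
            raise ValueError(
                f"target fraction {self.target_fraction} outside "
                f"[0, {CLOSE_PACKING:.4f}) (close packing bound)")

    @property
    def crowder_volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.crowder_radius ** 3


def sphere_overlap_volume(r1: float, r2: float, d: float) -> float:
    """Lens volume of two intersecting spheres (closed form)."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return 4.0 / 3.0 * math.pi * r ** 3
    return (math.pi * (r1 + r2 - d) ** 2
            * (d * d + 2.0 * d * (r1 + r2) - 3.0 * (r1 * r1 + r2 * r2)
               + 6.0 * r1 * r2) / (12.0 * d))


def available_volume(scene: Scene) -> float:
    """Container volume not occupied by the ribosome (A^3), at the
    equilibrium tether geometry (exit point at the container centre)."""
    if not np.isfinite(scene.container_radius):
        raise ValueError("available volume undefined for an unbounded scene")
    v_container = 4.0 / 3.0 * math.pi * scene.container_radius ** 3
    if scene.volume_denominator == "container":
        return v_container
    d = float(np.linalg.norm(scene.ribosome_center - scene.container_center))
    return v_container - sphere_overlap_volume(
        scene.container_radius, scene.ribosome_radius, d)


def crowder_count(target_fraction: float, scene: Scene) -> int:
    """Number of crowders realising the target excluded-volume
    fraction (rounded); the realised fraction is logged."""
    if not (0.0 <= target_fraction <= 0.74):
        raise ValueError(
            f"target fraction {target_fraction} outside [0, 0.74] "
            f"(close packing bound {CLOSE_PACKING:.4f})")
    n = round(target_fraction * available_volume(scene) / scene.crowder_volume)
    logger.info("crowding target %.3f -> %d crowders (realised %.4f)",
                target_fraction, n, realised_fraction(n, scene))
    return int(n)


def realised_fraction(n: int, scene: Scene) -> float:
    return n * scene.crowder_volume / available_volume(scene)


def _constraints_ok(c: np.ndarray, others: list[np.ndarray],
                    scene: Scene) -> bool:
    r = scene.crowder_radius
    if np.linalg.norm(c - scene.container_center) > scene.container_radius - r:
        return False
    # centre outside the ribosome sphere; residual surface overlap is
    # resolved by the soft boundary force during dynamics (full-body
    # exclusion leaves geometrically too little room at dense fractions)
    if np.linalg.norm(c - scene.ribosome_center) < scene.ribosome_radius:
        return False
    for o in others:
        if np.linalg.norm(c - o) < 2.0 * r:
            return False
    return True


def _project(c: np.ndarray, scene: Scene) -> np.ndarray:
    """Project a centre onto the container/ribosome constraints."""
    r = scene.crowder_radius
    d_vec = c - scene.container_center
    d = np.linalg.norm(d_vec)
    lim = scene.container_radius - r
    if d > lim:
        c = scene.container_center + d_vec * (lim / d)
    d_vec = c - scene.ribosome_center
    d = np.linalg.norm(d_vec)
    if d < scene.ribosome_radius and d > 0:
        c = scene.ribosome_center + d_vec * (scene.ribosome_radius / d)
    return c


def _relax_placement(n: int, scene: Scene, rng: np.random.Generator,
                     sweeps: int = 4000) -> Optional[np.ndarray]:
    """Overlap-relaxation packer for near-jamming fractions: start from
    random centres and repeatedly push overlapping pairs apart while
    re-projecting onto the geometric constraints."""
    r = scene.crowder_radius
    R = scene.container_radius - r
    pts = np.array([_project(rng.uniform(-R, R, 3) + scene.container_center,
                             scene) for _ in range(n)])
    target = 2.0 * r
    eye = np.eye(n, dtype=bool)
    for _ in range(sweeps):
        diff = pts[None, :, :] - pts[:, None, :]
        dist = np.linalg.norm(diff, axis=2)
        dist[eye] = np.inf
        overlap = dist < target
        if not overlap.any():
            ok = all(_constraints_ok(pts[i],
                                     [pts[j] for j in range(n) if j != i],
                                     scene) for i in range(n))
            if ok:
                return pts
        zero = dist < 1e-9
        if zero.any():
            diff[zero] = rng.standard_normal((int(zero.sum()), 3))
            dist[zero] = np.linalg.norm(diff[zero], axis=1)
        with np.errstate(invalid="ignore"):   # inf on the diagonal
            push = np.where(overlap, 0.55 * (target - dist) / dist, 0.0)
        pts -= (push[:, :, None] * diff).sum(axis=1)
        for i in range(n):
            pts[i] = _project(pts[i], scene)
    return None


def _fcc_sites(scene: Scene, rng: np.random.Generator,
               spacing: float) -> np.ndarray:
    """FCC lattice candidate sites (random orientation and offset)
    satisfying the container/ribosome constraints."""
    a = spacing * math.sqrt(2.0)
    R = scene.container_radius
    k = int(math.ceil(R / a)) + 1
    grid = np.arange(-k, k + 1) * a
    base = np.stack(np.meshgrid(grid, grid, grid), axis=-1).reshape(-1, 3)
    offsets = np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5],
                        [0, 0.5, 0.5]]) * a
    pts = (base[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    # random rotation (QR of a gaussian matrix) and offset
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    pts = pts @ q.T + rng.uniform(-0.5, 0.5, 3) * a + scene.container_center
    r = scene.crowder_radius
    ok = (np.linalg.norm(pts - scene.container_center, axis=1)
          <= scene.container_radius - r)
    ok &= (np.linalg.norm(pts - scene.ribosome_center, axis=1)
           >= scene.ribosome_radius)
    return pts[ok]


def place_crowders(n: int, scene: Scene, rng: np.random.Generator,
                   max_attempts: int = 100_000) -> np.ndarray:
    """Non-overlapping crowder centres inside the container.

    Constraints: centre within ``container_radius - crowder_radius`` of
    the container centre, centre outside the ribosome sphere, pairwise
    centre distance at least one crowder diameter.  Sequential
    rejection sampling is used first; because dart throwing jams well
    below close packing, dense fractions fall back to sites of a
    randomly oriented FCC lattice and finally to an overlap-relaxation
    packer.
    """
    if n < 0:
        raise ValueError("crowder count must be >= 0")
    if n == 0:
        return np.zeros((0, 3))
    # quick infeasibility bound: bodies cannot exceed close packing of
    # the whole container
    v_container = 4.0 / 3.0 * math.pi * scene.container_radius ** 3
    hard_max = int(CLOSE_PACKING * v_container / scene.crowder_volume)
    if n > hard_max:
        raise RuntimeError(
            f"could not place {n} crowders (close packing caps the "
            f"container at {hard_max}); lower the target crowding fraction")
    R = scene.container_radius - scene.crowder_radius
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n and attempts < max_attempts:
        attempts += 1
        c = rng.uniform(-R, R, 3) + scene.container_center
        if _constraints_ok(c, placed, scene):
            placed.append(c)
    if len(placed) == n:
        return np.asarray(placed)

    # dense regime: draw sites from a jittered FCC lattice
    spacing = 2.0 * scene.crowder_radius + 0.05
    best = len(placed)
    for _ in range(10):
        sites = _fcc_sites(scene, rng, spacing)
        if len(sites) >= n:
            pick = rng.choice(len(sites), size=n, replace=False)
            return sites[pick]
        best = max(best, len(sites))

    # near-jamming regime: overlap relaxation
    for _ in range(10):
        pts = _relax_placement(n, scene, rng)
        if pts is not None:
            return pts
    raise RuntimeError(
        f"could not place {n} crowders (achieved at most {best}); "
        f"lower the target crowding fraction")


class SynthesisHook:
    """Co-translational synthesis schedule.

    Residue k's beads appear at the exit point at iteration
    ``(k - 1) * rate`` with zero velocity; the new backbone bead is
    tethered to the exit particle and the previous tether is released.
    The final tether is released one period after the last residue
    appears, so the chain is complete and free after
    ``len(sequence) * rate`` iterations.
    """

    def __init__(self, chain: ProteinChain, scene: Scene, rate: int = 1000):
        if chain.synthesized_count != 0:
            raise ValueError("synthesis hook requires an unsynthesized chain")
        self.rate = int(rate)
        self.scene = scene
        l = len(chain)
        self._events = {(k - 1) * self.rate: k for k in range(1, l + 1)}
        self._events[l * self.rate] = 0   # 0 = final untether
        self._pending = sorted(self._events)

    def next_event(self, after: int) -> Optional[int]:
        for e in self._pending:
            if e >= after:
                return e
        return None

    def apply(self, iteration: int, system: ParticleSystem,
              chain: ProteinChain, compiled: CompiledState) -> None:
        if iteration not in self._events or iteration not in self._pending:
            return
        self._pending.remove(iteration)
        k = self._events[iteration]
        if k == 0:  # synthesis complete: release the last tether
            row = compiled.tether_rows[len(chain)]
            compiled.sp_active[row] = 0
            return
        exit_pos = system.pos[self.scene.exit_particle_id]
        out_dir = exit_pos - self.scene.ribosome_center
        nrm = np.linalg.norm(out_dir)
        out_dir = out_dir / nrm if nrm > 0 else np.array([0.0, 0.0, 1.0])
        bb, sc = chain.particle_ids[k - 1]
        # small deterministic offsets avoid exactly coincident beads
        system.pos[bb] = exit_pos + 0.5 * out_dir
        system.vel[bb] = 0.0
        system.active[bb] = True
        if sc is not None:
            lateral = np.cross(out_dir, [1.0, 0.0, 0.0])
            if np.linalg.norm(lateral) < 1e-9:
                lateral = np.cross(out_dir, [0.0, 1.0, 0.0])
            lateral /= np.linalg.norm(lateral)
            system.pos[sc] = exit_pos + 1.0 * out_dir + 0.5 * lateral
            system.vel[sc] = 0.0
            system.active[sc] = True
        chain.synthesized_count = k
        compiled.sp_active[compiled.tether_rows[k]] = 1
        if k > 1:
            compiled.sp_active[compiled.tether_rows[k - 1]] = 0


def build_cell(sequence: str, ss: str, fraction: float, rng,
               ff: Optional[ForceFieldParams] = None,
               lp: Optional[LangevinParams] = None,
               container_radius: float = 50.0,
               ribosome_radius: float = 100.0,
               crowder_radius: float = 15.0,
               crowder_mass: float = 150.0,
               ) -> tuple[ParticleSystem, ProteinChain, Scene]:
    """Assemble the full particle system for one synthesis simulation.

    The chain's beads start inactive (to be activated by the synthesis
    hook); the exit particle sits at the container centre on the
    ribosome surface and carries ribosome-scale mass.
    """
    if ff is None or lp is None:
        dff, dlp = default_params()
        ff = ff or dff
        lp = lp or dlp
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    chain = build_chain(sequence, ss, ff, lp)
    scene = Scene(container_radius=container_radius,
                  ribosome_radius=ribosome_radius,
                  ribosome_center=np.array([0.0, 0.0, -ribosome_radius]),
                  crowder_radius=crowder_radius, crowder_mass=crowder_mass,
                  target_fraction=fraction)
    n_crowd = crowder_count(fraction, scene) if fraction > 0 else 0
    crowder_pos = place_crowders(n_crowd, scene, rng)

    system = ParticleSystem.from_particles(chain.particles)
    system.active[:] = False  # synthesized later

    def _append(pos, mass, radius, role, movable=True):
        i = system.n
        system.pos = np.vstack([system.pos, np.asarray(pos, float)[None]])
        system.vel = np.vstack([system.vel, np.zeros((1, 3))])
        system.mass = np.append(system.mass, mass)
        system.solvent_radius = np.append(system.solvent_radius, radius)
        system.role = np.append(system.role, np.int8(role))
        system.residue_index = np.append(system.residue_index, np.int32(-1))
        system.hydrophobic = np.append(system.hydrophobic, False)
        system.movable = np.append(system.movable, movable)
        system.active = np.append(system.active, True)
        return i

    rib_id = _append(scene.ribosome_center, 1e6, scene.ribosome_radius,
                     Role.RIBOSOME, movable=False)
    # the exit particle carries ribosome-scale mass, approximating the
    # moment of inertia of the ribosome as a whole
    exit_id = _append(scene.container_center, 1e6, 2.0, Role.EXIT_POINT,
                      movable=True)
    scene.exit_particle_id = exit_id
    for c in crowder_pos:
        cid = _append(c, scene.crowder_mass, scene.crowder_radius,
                      Role.CROWDER, movable=True)
        scene.crowder_ids.append(cid)
    _ = rib_id
    return system, chain, scene


def sampling_plan(n_proteins: int = 12, replicates: int = 100,
                  post_iterations: int = 1_000_000,
                  sample_interval: int = 1000) -> dict:
    """Bookkeeping of the crowding study's sampling scheme."""
    per_replicate = post_iterations // sample_interval
    per_protein_level = per_replicate * replicates
    return {
        "samples_per_replicate": per_replicate,
        "replicates": replicates,
        "samples_per_protein_per_level": per_protein_level,
        "n_proteins": n_proteins,
        "total_conformations_per_level": per_protein_level * n_proteins,
    }


def run_crowding_simulation(sequence: str, ss: str, fraction: float,
                            seed: int,
                            ff: Optional[ForceFieldParams] = None,
                            lp: Optional[LangevinParams] = None,
                            post_iterations: int = 1_000_000,
                            sample_interval: int = 1000,
                            synthesis_rate: int = 1000,
                            engine: str = "fast",
                            container_radius: float = 50.0,
                            pre_equilibration: int = 5000,
                            dry_run: bool = False):
    """One co-translational synthesis into the crowded cell followed by
    ``post_iterations`` of free folding, sampling protein conformations
    every ``sample_interval`` iterations.

    Before synthesis begins the crowder bath alone is integrated for
    ``pre_equilibration`` iterations so the protein emerges into a
    settled cell rather than a freshly packed one.  With
    ``dry_run=True`` no integration is performed; the sampling plan for
    this configuration is returned instead.
    """
    l = len(sequence)
    n_steps = l * synthesis_rate + post_iterations
    if dry_run:
        plan = sampling_plan(1, 1, post_iterations, sample_interval)
        plan.update(total_iterations=n_steps,
                    synthesis_iterations=l * synthesis_rate)
        return plan
    rng = np.random.default_rng(seed)
    system, chain, scene = build_cell(sequence, ss, fraction, rng,
                                      ff=ff, lp=lp,
                                      container_radius=container_radius)
    if ff is None or lp is None:
        dff, dlp = default_params()
        ff = ff or dff
        lp = lp or dlp
    if pre_equilibration > 0 and len(scene.crowder_ids) > 0:
        run(system, None, scene, ff, lp, pre_equilibration,
            pre_equilibration, seed=seed + 2**30, engine=engine)
    hook = SynthesisHook(chain, scene, rate=synthesis_rate)
    return run(system, chain, scene, ff, lp, n_steps, sample_interval,
               seed=seed, hooks=[hook], engine=engine)


def run_crowding_sweep(sequence: str, ss: str, fractions, replicates: int,
                       seed: int, out_dir, name: str = "protein",
                       **kwargs) -> dict:
    """Repeat :func:`run_crowding_simulation` over fractions and
    replicates, writing one trajectory per (fraction, replicate) and a
    JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"protein": name, "sequence": sequence, "ss": ss, "runs": []}
    for fraction in fractions:
        scene = Scene(target_fraction=fraction)
        n = crowder_count(fraction, scene) if fraction > 0 else 0
        for rep in range(replicates):
            run_seed = seed + 10_000 * int(round(1000 * fraction)) + rep
            traj = run_crowding_simulation(sequence, ss, fraction, run_seed,
                                           **kwargs)
            fname = f"{name}_f{fraction:.2f}_r{rep}.traj.gz"
            traj.save(out_dir / fname)
            manifest["runs"].append({
                "fraction": fraction, "replicate": rep, "seed": run_seed,
                "n_crowders": n,
                "realised_fraction": realised_fraction(n, scene),
                "trajectory": fname,
            })
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
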