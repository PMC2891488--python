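"""Iterative solution of the Langevin equation of motion.

Each iteration updates, per particle, ``a = (F - gamma_eff v + R) / m``
with a semi-implicit (velocity-first) Euler scheme: the drag enters as
a multiplicative decay of the current velocity, spring/steric/boundary
forces and solvent-kick impulses are then added, speeds are clamped at
``speed_cap`` (a stability device, not physics) and positions advance
by ``v dt``.  The ribosome particle is held immobile.

Two engines produce trajectories: ``fast`` (the numba kernel, used for
production runs) and ``reference`` (plain numpy, one step at a time).
Both are deterministic given a seed, but draw their random numbers from
different generators, so only the deterministic parts (kicks disabled)
are comparable across engines.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from . import _kernel
from .forces import total_force
from .model_core import (ForceFieldParams, LangevinParams, ParticleSystem,
                         ProteinChain, Role, Spring)
from .solvent import compute_exposure, fibonacci_directions, sample_kicks

__all__ = ["Trajectory", "IntegrationError", "CompiledState", "step", "run",
           "config_digest"]

_FAR_AWAY = 1e9


class IntegrationError(RuntimeError):
    """Raised when a coordinate becomes non-finite during integration."""


def config_digest(ff: ForceFieldParams, lp: LangevinParams, scene=None) -> str:
    """Short hash identifying the effective parameter set."""
    blob = repr((sorted(ff.__dict__.items(), key=lambda kv: kv[0]),
                 sorted(lp.__dict__.items(), key=lambda kv: kv[0]),
                 None if scene is None else sorted(
                     (k, v) for k, v in scene.__dict__.items()
                     if not isinstance(v, (list, np.ndarray)))))
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


@dataclass
class Trajectory:
    """Conformation samples at fixed iteration intervals.

    ``coords`` holds the recorded particle subset (protein beads by
    default); the pre-run state is kept separately in ``initial``.
    """

    iterations: np.ndarray            # (k,) strictly increasing
    coords: np.ndarray                # (k, m, 3)
    initial: np.ndarray               # (m, 3) state at iteration 0
    record_index: np.ndarray          # (m,) particle indices recorded
    roles: np.ndarray                 # (m,) role codes of recorded particles
    residue_index: np.ndarray         # (m,)
    sample_interval: int
    seed: int
    config_digest: str
    sequence: str = ""
    ss: str = ""

    @property
    def n_samples(self) -> int:
        return len(self.iterations)

    def backbone_coords(self) -> np.ndarray:
        """(k, L, 3) backbone-bead coordinates in residue order."""
        mask = self.roles == int(Role.BACKBONE)
        order = np.argsort(self.residue_index[mask])
        return self.coords[:, mask, :][:, order, :]

    def save(self, path) -> None:
        """Self-describing text format (gzipped if path ends in .gz)."""
        path = str(path)
        header = {
            "sequence": self.sequence, "ss": self.ss,
            "sample_interval": int(self.sample_interval),
            "seed": int(self.seed), "config_digest": self.config_digest,
            "n_samples": int(self.n_samples),
            "record_index": self.record_index.tolist(),
            "roles": self.roles.tolist(),
            "residue_index": self.residue_index.tolist(),
        }
        opener = gzip.open if path.endswith(".gz") else open
        with opener(path, "wt") as fh:
            fh.write("#crowdfold-trajectory 1\n")
            fh.write(json.dumps(header) + "\n")
            fh.write("#initial\n")
            for x, y, z in self.initial:
                fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
            for it, frame in zip(self.iterations, self.coords):
                fh.write(f"#sample {int(it)}\n")
                for x, y, z in frame:
                    fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")

    @classmethod
    def load(cls, path) -> "Trajectory":
        path = str(path)
        opener = gzip.open if path.endswith(".gz") else open
        with opener(path, "rt") as fh:
            magic = fh.readline().strip()
            if magic != "#crowdfold-trajectory 1":
                raise ValueError(f"{path}: not a crowdfold trajectory "
                                 f"(first line {magic!r})")
            header = json.loads(fh.readline())
            m = len(header["record_index"])
            blocks: list[np.ndarray] = []
            iters: list[int] = []
            line = fh.readline()
            while line:
                tag = line.strip().split()
                if not tag or not tag[0].startswith("#"):
                    raise ValueError(f"{path}: malformed block header {line!r}")
                if tag[0] == "#sample":
                    iters.append(int(tag[1]))
                rows = [fh.readline().split() for _ in range(m)]
                blocks.append(np.asarray(rows, dtype=float))
                line = fh.readline()
        initial = blocks[0]
        coords = (np.stack(blocks[1:]) if len(blocks) > 1
                  else np.zeros((0, m, 3)))
        return cls(
            iterations=np.asarray(iters, dtype=int), coords=coords,
            initial=initial,
            record_index=np.asarray(header["record_index"], dtype=int),
            roles=np.asarray(header["roles"], dtype=np.int8),
            residue_index=np.asarray(header["residue_index"], dtype=np.int32),
            sample_interval=header["sample_interval"], seed=header["seed"],
            config_digest=header["config_digest"],
            sequence=header["sequence"], ss=header["ss"])


@dataclass
class CompiledState:
    """Flat-array view of a system + spring network for the kernel."""

    system: ParticleSystem
    sp_i: np.ndarray
    sp_j: np.ndarray
    sp_k: np.ndarray
    sp_L0: np.ndarray
    sp_active: np.ndarray
    excl: np.ndarray
    vdw_r: np.ndarray
    bb_idx: np.ndarray
    tether_rows: dict[int, int] = field(default_factory=dict)  # residue -> spring row
    exposure: Optional[np.ndarray] = None
    sp_cat: Optional[np.ndarray] = None  # 0 = chain spring, 1 = tether

    def spring_list(self) -> list[Spring]:
        """Active extra (tether) springs as Spring objects, for the
        reference force path."""
        out = []
        for s in range(len(self.sp_i)):
            if self.sp_active[s] and self.sp_cat[s] == 1:
                out.append(Spring(int(self.sp_i[s]), int(self.sp_j[s]),
                                  float(self.sp_L0[s]), float(self.sp_k[s]),
                                  "tether"))
        return out


def compile_state(system: ParticleSystem, chain: Optional[ProteinChain],
                  scene, ff: ForceFieldParams) -> CompiledState:
    n = system.n
    springs = list(chain.springs) if chain is not None else []
    n_chain = len(springs)
    # tether rows: one per residue, toggled by the synthesis hook
    tether_rows: dict[int, int] = {}
    exit_idx = -1 if scene is None else scene.exit_particle_id
    if chain is not None and scene is not None and exit_idx >= 0:
        for res_i, (bb, _) in enumerate(chain.particle_ids, start=1):
            tether_rows[res_i] = n_chain + res_i - 1

    n_rows = n_chain + len(tether_rows)
    sp_i = np.zeros(n_rows, dtype=np.int64)
    sp_j = np.zeros(n_rows, dtype=np.int64)
    sp_k = np.zeros(n_rows)
    sp_L0 = np.zeros(n_rows)
    sp_active = np.zeros(n_rows, dtype=np.uint8)
    sp_cat = np.zeros(n_rows, dtype=np.int8)
    for s, sp in enumerate(springs):
        sp_i[s], sp_j[s] = sp.i, sp.j
        sp_k[s], sp_L0[s] = sp.stiffness, sp.rest_length
        sp_active[s] = 1
    if chain is not None:
        for res_i, row in tether_rows.items():
            sp_i[row] = chain.particle_ids[res_i - 1][0]
            sp_j[row] = exit_idx
            sp_k[row] = ff.k_tether
            sp_L0[row] = ff.cov_ca_ca
            sp_active[row] = 0
            sp_cat[row] = 1

    excl = np.zeros((n, n), dtype=np.uint8)
    for sp in springs:
        if sp.category == "cov":
            excl[sp.i, sp.j] = 1
            excl[sp.j, sp.i] = 1

    from .model_core import role_name
    vdw_r = np.zeros(n)
    for i in range(n):
        name = role_name(system.role[i])
        vdw_r[i] = ff.vdw_radii.get(name, 0.0)

    bb_idx = (np.asarray(chain.backbone_ids, dtype=np.int64)
              if chain is not None else np.zeros(0, dtype=np.int64))

    st = CompiledState(system=system, sp_i=sp_i, sp_j=sp_j, sp_k=sp_k,
                       sp_L0=sp_L0, sp_active=sp_active, excl=excl,
                       vdw_r=vdw_r, bb_idx=bb_idx, tether_rows=tether_rows,
                       exposure=np.zeros(n))
    st.sp_cat = sp_cat
    return st


def _maxrep_matrix(ff: ForceFieldParams) -> np.ndarray:
    """(5, 5) role-pair max-repulsion matrix for the fast kernel.

    The kernel implements the default linear soft-core ramp with
    contact = r_i + r_j; tabulated profile entries are approximated by
    a ramp scaled to the profile's peak (exact profiles are available
    through the reference engine).
    """
    from .model_core import Role
    names = {r.name.lower(): int(r) for r in Role}
    m = np.ones((len(names), len(names)))
    for (a, b), v in ff.vdw_table.items():
        if a not in names or b not in names:
            continue
        arr = np.asarray(v, dtype=float)
        val = float(arr[1]) if arr.ndim == 1 else float(arr[:, 1].max())
        m[names[a], names[b]] = val
        m[names[b], names[a]] = val
    return m


def _scene_arrays(scene):
    if scene is None:
        return (np.zeros(3), np.inf, np.array([_FAR_AWAY, 0.0, 0.0]),
                -_FAR_AWAY, -1)
    return (np.asarray(scene.container_center, dtype=float),
            float(scene.container_radius),
            np.asarray(scene.ribosome_center, dtype=float),
            float(scene.ribosome_radius),
            int(scene.exit_particle_id))


def step(system: ParticleSystem, chain: Optional[ProteinChain], scene,
         ff: ForceFieldParams, lp: LangevinParams,
         exposure=None, rng: Optional[np.random.Generator] = None,
         extra_springs: Sequence[Spring] = ()) -> ParticleSystem:
    """One reference integration step, in place (returns the system)."""
    if exposure is None:
        exposure = compute_exposure(system, lp)
    rep = total_force(system, chain, scene, ff, extra_springs=extra_springs,
                      breakdown=False)
    fac = lp.gamma * exposure.area * lp.dt / system.mass
    np.clip(fac, None, _kernel.MAX_DRAG_FACTOR, out=fac)
    mob = system.active & system.movable
    system.vel[~mob] = 0.0
    system.vel[mob] = (system.vel[mob] * (1.0 - fac[mob, None])
                       + rep.total[mob] * (lp.dt / system.mass[mob, None]))
    if rng is not None and lp.kick_rate > 0:
        system.vel += sample_kicks(system, exposure, lp, rng)
    speed = np.linalg.norm(system.vel, axis=1)
    over = speed > lp.speed_cap
    if np.any(over):
        system.vel[over] *= (lp.speed_cap / speed[over])[:, None]
    system.pos[mob] += system.vel[mob] * lp.dt
    if not np.all(np.isfinite(system.pos)):
        bad = int(np.argwhere(~np.isfinite(system.pos))[0][0])
        rep2 = total_force(system, chain, scene, ff, extra_springs=extra_springs)
        terms = {k: rep2.terms[k][bad].tolist() for k in rep2.terms}
        raise IntegrationError(
            f"non-finite coordinate on particle {bad} "
            f"(role {int(system.role[bad])}); force breakdown: {terms}")
    return system


def run(system: ParticleSystem, chain: Optional[ProteinChain], scene,
        ff: ForceFieldParams, lp: LangevinParams,
        n_steps: int, sample_interval: int, seed: int,
        hooks: Iterable = (), engine: str = "fast",
        record_roles: tuple = (Role.BACKBONE, Role.SIDECHAIN),
        compiled: Optional[CompiledState] = None) -> Trajectory:
    """Integrate ``n_steps`` iterations, sampling every
    ``sample_interval``.

    Samples are taken at iterations ``k * sample_interval`` for
    ``k = 1 .. floor(n_steps / sample_interval)``; the initial state is
    stored separately on the trajectory.  Hooks (e.g. the synthesis
    schedule) are consulted for their next event iteration and applied
    when the integration reaches it.  Identical seed, engine and
    configuration give identical trajectories.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if sample_interval < 1:
        raise ValueError("sample_interval must be >= 1")
    hooks = list(hooks)
    if compiled is None:
        compiled = compile_state(system, chain, scene, ff)
    rec = np.array([i for i in range(system.n)
                    if system.role[i] in tuple(int(r) for r in record_roles)],
                   dtype=int)
    container_center, container_radius, rib_center, rib_radius, exit_idx = \
        _scene_arrays(scene)
    rays = np.asarray(fibonacci_directions(lp.exposure_rays))
    maxrep = _maxrep_matrix(ff)
    master = np.random.default_rng(seed)

    samples: list[np.ndarray] = []
    sample_iters: list[int] = []
    initial = system.pos[rec].copy()

    def _due_hooks(it: int):
        for h in hooks:
            nxt = h.next_event(it)
            if nxt is not None and nxt == it:
                h.apply(it, system, chain, compiled)

    it = 0
    _due_hooks(0)
    while it < n_steps:
        target = n_steps
        k_next = (it // sample_interval + 1) * sample_interval
        if k_next <= n_steps:
            target = min(target, k_next)
        for h in hooks:
            nxt = h.next_event(it + 1)
            if nxt is not None and it < nxt <= target:
                target = min(target, nxt)
        chunk = target - it
        chunk_seed = int(master.integers(0, 2**31 - 1))
        if engine == "fast":
            n_bb = len(compiled.bb_idx)
            if chain is not None and chain.synthesized_count:
                n_bb = chain.synthesized_count
            status, bad = _kernel.run_chunk(
                system.pos, system.vel, system.mass, system.solvent_radius,
                compiled.vdw_r, system.role.astype(np.int64),
                system.hydrophobic.astype(np.uint8),
                system.movable.astype(np.uint8),
                system.active.astype(np.uint8),
                compiled.sp_i, compiled.sp_j, compiled.sp_k, compiled.sp_L0,
                compiled.sp_active, compiled.excl,
                compiled.bb_idx, n_bb,
                ff.hb_threshold, ff.hb_strength, ff.hb_min_separation,
                0.5 * ff.cov_ca_ca,
                container_center, container_radius, rib_center, rib_radius,
                ff.k_boundary, ff.k_tether, exit_idx,
                lp.gamma, lp.kick_speed, lp.kick_rate,
                lp.hydrophobic_multiplier, lp.dt, lp.speed_cap,
                lp.neighbor_cutoff, rays, lp.exposure_interval, maxrep,
                chunk, it, chunk_seed, compiled.exposure)
            if status >= 0:
                raise IntegrationError(
                    f"non-finite coordinate on particle {bad} at iteration "
                    f"{it + status}")
        elif engine == "reference":
            rng = np.random.default_rng(chunk_seed)
            extra = compiled.spring_list()
            for _ in range(chunk):
                step(system, chain, scene, ff, lp, exposure=None, rng=rng,
                     extra_springs=extra)
        else:
            raise ValueError(f"unknown engine {engine!r}")
        it = target
        _due_hooks(it)
        if it % sample_interval == 0 and it > 0:
            sample_iters.append(it)
            samples.append(system.pos[rec].copy())

    coords = (np.stack(samples) if samples
              else np.zeros((0, len(rec), 3)))
    return Trajectory(
        iterations=np.asarray(sample_iters, dtype=int), coords=coords,
        initial=initial, record_index=rec,
        roles=system.role[rec].copy(),
        residue_index=system.residue_index[rec].copy(),
        sample_interval=sample_interval, seed=seed,
        config_digest=config_digest(ff, lp, scene),
        sequence="" if chain is None else chain.sequence,
        ss="" if chain is None else chain.ss)
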