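"""Structure prediction from folding-trajectory conformation pools.

The protocol: many co-translational folding trajectories are produced
with different seeds (uncrowded, synthesis from the ribosome), each
integrated for ``6000 l + 400000`` iterations (l = chain length) with
40 structures sampled at equal intervals from iteration ``6000 l`` to
the end.  The pooled structures are ranked by similarity to the pool's
consensus contact map (rewarding contacts shared with the consensus
and penalising their absence), the top of the ranking is optionally
rescored by a pluggable model-quality scorer, and the final five are
filtered for diversity: whenever two of the current top five are very
similar (at least 90% of residues within 7 A after optimal
superposition) the lower-scoring one is replaced by the next
candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .analysis import ContactMap, contact_map, superpose
from .model_core import ForceFieldParams, LangevinParams, default_params
from .integrator import run
from .synthesis_crowding import SynthesisHook, build_cell

__all__ = ["ConformationPool", "generate_pool", "pool_plan", "consensus_map",
           "consensus_score", "very_similar", "select_predictions",
           "PredictionResult", "PER_RESIDUE_ITERS", "EXTRA_ITERS",
           "N_SAMPLES_PER_TRAJ", "DEFAULT_N_TRAJ"]

PER_RESIDUE_ITERS = 6000
EXTRA_ITERS = 400_000
N_SAMPLES_PER_TRAJ = 40
DEFAULT_N_TRAJ = 150


@dataclass
class ConformationPool:
    """Sampled structures with provenance and contact maps."""

    sequence: str
    ss: str
    conformations: np.ndarray          # (m, L, 3) backbone coordinates
    provenance: list                   # (trajectory seed, iteration) per member
    maps: Optional[list[ContactMap]] = None
    scores: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return self.conformations.shape[0]

    def contact_maps(self) -> list[ContactMap]:
        if self.maps is None:
            self.maps = [contact_map(c, self.ss) for c in self.conformations]
        return self.maps


def pool_plan(seq_length: int, n_traj: int = DEFAULT_N_TRAJ,
              per_residue_iters: int = PER_RESIDUE_ITERS,
              extra_iters: int = EXTRA_ITERS,
              n_samples: int = N_SAMPLES_PER_TRAJ) -> dict:
    """Iteration/sampling bookkeeping for a prediction pool."""
    budget = per_residue_iters * seq_length + extra_iters
    return {
        "per_trajectory_iterations": budget,
        "sampling_starts_at": per_residue_iters * seq_length,
        "sample_interval": extra_iters // n_samples,
        "samples_per_trajectory": n_samples,
        "n_trajectories": n_traj,
        "pool_size": n_traj * n_samples,
    }


def generate_pool(sequence: str, ss: str, n_traj: int = DEFAULT_N_TRAJ,
                  base_seed: int = 0,
                  ff: Optional[ForceFieldParams] = None,
                  lp: Optional[LangevinParams] = None,
                  per_residue_iters: int = PER_RESIDUE_ITERS,
                  extra_iters: int = EXTRA_ITERS,
                  n_samples: int = N_SAMPLES_PER_TRAJ,
                  synthesis_rate: int = 1000,
                  engine: str = "fast",
                  dry_run: bool = False):
    """Produce the conformation pool (or, with ``dry_run``, its plan).

    Trajectory k uses seed ``base_seed + k``.  Synthesis is uncrowded
    and unbounded (ribosome and exit tether only); sampling keeps the
    ``n_samples`` conformations after iteration
    ``per_residue_iters * l``.
    """
    l = len(sequence)
    plan = pool_plan(l, n_traj, per_residue_iters, extra_iters, n_samples)
    if dry_run:
        return plan
    if ff is None or lp is None:
        dff, dlp = default_params()
        ff = ff or dff
        lp = lp or dlp
    interval = plan["sample_interval"]
    start = plan["sampling_starts_at"]
    budget = plan["per_trajectory_iterations"]
    confs = []
    provenance = []
    for k in range(n_traj):
        seed = base_seed + k
        system, chain, scene = build_cell(sequence, ss, 0.0, seed,
                                          ff=ff, lp=lp,
                                          container_radius=np.inf)
        hook = SynthesisHook(chain, scene, rate=synthesis_rate)
        traj = run(system, chain, scene, ff, lp, budget, interval,
                   seed=seed, hooks=[hook], engine=engine)
        bb = traj.backbone_coords()
        keep = traj.iterations > start
        for it, conf in zip(traj.iterations[keep], bb[keep]):
            confs.append(conf)
            provenance.append((seed, int(it)))
    return ConformationPool(sequence=sequence, ss=ss,
                            conformations=np.stack(confs),
                            provenance=provenance)


def consensus_map(pool: ConformationPool) -> ContactMap:
    """Element-wise mean of the pool members' binary contact maps."""
    if len(pool) == 0:
        raise ValueError("cannot build a consensus from an empty pool")
    maps = pool.contact_maps()
    mean = np.mean([m.values for m in maps], axis=0)
    return ContactMap(values=mean, eligible=maps[0].eligible)


def consensus_score(conf_map: ContactMap, mean_map: ContactMap) -> float:
    """Similarity of one structure's contact map to the consensus.

    Over eligible pairs i < j the consensus weight is added where the
    structure has the contact and subtracted where it lacks it, so the
    score rewards contacts that should be present and penalises their
    absence.
    """
    if conf_map.values.shape != mean_map.values.shape:
        raise ValueError("contact map shapes differ")
    if not np.array_equal(conf_map.eligible, mean_map.eligible):
        raise ValueError("contact map eligibility masks differ")
    upper = np.triu(mean_map.eligible, k=1)
    sign = np.where(conf_map.values > 0.5, 1.0, -1.0)
    return float((mean_map.values * sign)[upper].sum())


def very_similar(a: np.ndarray, b: np.ndarray, fraction: float = 0.9,
                 cutoff: float = 7.0) -> bool:
    """True when at least ``fraction`` of residues lie within
    ``cutoff`` of their counterparts after optimal superposition."""
    R, t, _ = superpose(a, b)
    d = np.linalg.norm(a @ R.T + t - b, axis=1)
    return float(np.mean(d < cutoff)) >= fraction


@dataclass
class PredictionResult:
    indices: list[int]          # pool indices of the final predictions
    scores: list[float]         # rescored scores, final order
    consensus_scores: np.ndarray  # per pool member
    decisions: list[str] = field(default_factory=list)

    def conformations(self, pool: ConformationPool) -> np.ndarray:
        return pool.conformations[self.indices]


def select_predictions(pool: ConformationPool,
                       scorer: Optional[Callable] = None,
                       k_shortlist: int = 20, k_final: int = 5
                       ) -> PredictionResult:
    """Rank the pool, rescore the shortlist, enforce diversity.

    ``scorer`` maps a conformation to a quality score (higher is
    better); by default the consensus score is kept (the scorer slot
    accepts any external model-quality program's ranking).  Ties break
    toward earlier pool provenance, so the outcome is deterministic
    given pool order.
    """
    m = len(pool)
    if m == 0:
        raise ValueError("empty conformation pool")
    mean_map = consensus_map(pool)
    maps = pool.contact_maps()
    cons = np.array([consensus_score(cm, mean_map) for cm in maps])
    pool.scores = cons
    order = sorted(range(m), key=lambda i: (-cons[i], i))
    shortlist = order[:k_shortlist]
    if scorer is None:
        rescored = {i: cons[i] for i in shortlist}
    else:
        rescored = {i: float(scorer(pool.conformations[i])) for i in shortlist}
    candidates = sorted(shortlist, key=lambda i: (-rescored[i], i))

    decisions: list[str] = []
    top = candidates[:k_final]
    pointer = len(top)
    while True:
        drop = None
        for a in range(len(top)):
            for b in range(a + 1, len(top)):
                if very_similar(pool.conformations[top[a]],
                                pool.conformations[top[b]]):
                    drop = top[b] if rescored[top[b]] <= rescored[top[a]] \
                        else top[a]
                    break
            if drop is not None:
                break
        if drop is None:
            break
        top.remove(drop)
        if pointer < len(candidates):
            promoted = candidates[pointer]
            pointer += 1
            top.append(promoted)
            top.sort(key=lambda i: (-rescored[i], i))
            decisions.append(f"dropped {drop} (similar), promoted {promoted}")
        else:
            decisions.append(f"dropped {drop} (similar), pool exhausted")
            if not top:
                break
    return PredictionResult(indices=top,
                            scores=[rescored[i] for i in top],
                            consensus_scores=cons, decisions=decisions)
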