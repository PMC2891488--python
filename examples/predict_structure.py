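"""Miniature structure-prediction run.

Generates a small conformation pool from repeated co-translational
folding trajectories (2 trajectories x 5 samples at a reduced
iteration budget; the full protocol uses 150 x 40), ranks the pool by
similarity to its consensus contact map and selects a diverse top set.
"""

from crowdfold.model_core import default_params
from crowdfold.prediction import (consensus_map, generate_pool, pool_plan,
                                  select_predictions)

seq = "LSLSLSLSLSLSLSLSLSLS"
ss = "C" * 20

full = pool_plan(seq_length=len(seq))
print(f"full protocol for {len(seq)} residues: "
      f"{full['n_trajectories']} trajectories x "
      f"{full['samples_per_trajectory']} samples = {full['pool_size']} "
      f"structures, {full['per_trajectory_iterations']} iterations each")

ff, lp = default_params()
lp.exposure_interval = 4
pool = generate_pool(seq, ss, n_traj=2, base_seed=11, ff=ff, lp=lp,
                     per_residue_iters=300, extra_iters=5000, n_samples=5,
                     synthesis_rate=300)
print(f"\nreduced pool: {len(pool)} conformations")

mean_map = consensus_map(pool)
print(f"consensus contact occupancy (eligible pairs): "
      f"{mean_map.values[mean_map.eligible].mean():.3f}")

result = select_predictions(pool)
print(f"selected {len(result.indices)} diverse predictions")
for rank, (idx, score) in enumerate(zip(result.indices, result.scores), 1):
    seed, iteration = pool.provenance[idx]
    print(f"  rank {rank}: pool member {idx} (seed {seed}, "
          f"iteration {iteration}), consensus score {score:.2f}")
for line in result.decisions:
    print(f"  diversity: {line}")
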