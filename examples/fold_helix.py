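"""Fold a poly-alanine helix from an extended start.

Builds a 12-residue chain whose secondary structure is all-helix, runs
the Langevin integrator for 30,000 iterations and compares the final
backbone to an ideal alpha helix.  A TM score above 0.3 means the
chain has found a roughly helical topology from the secondary-structure
springs alone.
"""

from crowdfold.analysis import tm_score
from crowdfold.integrator import run
from crowdfold.io import make_fixture
from crowdfold.model_core import build_chain, default_params, make_system

ff, lp = default_params()
chain = build_chain("A" * 12, "H" * 12, ff, lp)
system = make_system(chain, ff=ff)

traj = run(system, chain, None, ff, lp, n_steps=30_000,
           sample_interval=1000, seed=3)

ideal = make_fixture("ideal_helix", length=12)
final = traj.backbone_coords()[-1]
score = tm_score(final, ideal.ca)
print(f"samples: {traj.n_samples}")
print(f"TM score of final conformation vs ideal helix: {score:.3f}")
print("roughly native-like topology" if score > 0.3 else "not yet helical")
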