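# crowdfold

Coarse-grained Langevin protein folding in a crowded simulated cell.

`crowdfold` is for structural bioinformaticians who want to study how
macromolecular crowding and co-translational synthesis shape protein
folding, with a model fast enough to run many proteins, many crowding
levels and many random repetitions on a desktop — and that doubles as a
template-free structure predictor.  The model is native-blind: it
contains no Gō-style bias toward known native contacts.

## The model

Each residue is reduced to two beads: a backbone bead at the Cα
position and a side-chain bead at the side-chain centroid (glycine has
none).  Particle motion follows the Langevin equation, solved
iteratively per particle:

    a = (F − γ_eff v + R) / m

where `F` is a sum of pairwise force terms

    F = F_cov + F_bb + F_sc + F_vdw + F_hb  (+ boundary restraints)

* `F_cov` — stiff springs between covalently bonded beads,
* `F_bb` — springs between backbone beads at sequence separations 2
  and 3 with rest lengths set by the residues' three-state secondary
  structure (ideal-helix and ideal-strand geometry),
* `F_sc` — springs orienting each side chain against the flanking
  backbone beads,
* `F_vdw` — purely repulsive steric ramp, zero beyond the contact
  distance,
* `F_hb` — a short-range attraction between backbone virtual H/O
  sites, gated by a distance threshold.

The solvent is hybrid implicit–explicit: drag (`−γ_eff v`) and random
kicks (`R`) act only on the solvent-exposed part of each bead's
surface, estimated by ray casting against neighbouring solvent
spheres.  All kicks carry the same speed and arrive in Poisson numbers
proportional to accessible area; kicks from blocked directions are
discarded.  Hydrophobic side-chain beads are kicked at a higher rate,
which drives their burial and hence hydrophobic collapse — the model's
only use of hydrophobicity.

The simulated cell is a 100 Å-diameter container holding the protein
and inert crowder spheres (diameter 30 Å, mass 150 bead masses — the
excluded volume of a ~75-residue protein) at a target fraction of the
ribosome-free container volume.  A heavy ribosome sphere (radius
100 Å) carries a synthesis exit point on its surface, tethered to the
container centre; the chain is synthesized one residue per 1000
iterations from that point.

For structure prediction, many seeded folding trajectories are pooled
(`6000·l + 400000` iterations each, 40 samples per trajectory, 150
trajectories), pool members are ranked by similarity to the pool's
consensus contact map, and the top five are filtered for diversity.

## Worked example

```python
from crowdfold.model_core import build_chain, default_params, make_system
from crowdfold.integrator import run
from crowdfold.io import make_fixture
from crowdfold.analysis import tm_score

ff, lp = default_params()
chain = build_chain("A" * 12, "H" * 12, ff, lp)
system = make_system(chain, ff=ff)
traj = run(system, chain, None, ff, lp, n_steps=30_000,
           sample_interval=1000, seed=3)
ideal = make_fixture("ideal_helix", length=12)
print(tm_score(traj.backbone_coords()[-1], ideal.ca))
```

This folds a poly-alanine 12-mer from an extended start with all-helix
secondary structure and prints

```
0.307
```

— the TM score of the final conformation against an ideal α-helix.
Scores above 0.3 indicate a roughly native-like topology (random
structure pairs average ~0.17), so the secondary-structure springs
alone recover a helical fold here.  `examples/` contains one short
script per capability: helix folding, hydrophobic collapse, crowded
synthesis, structure prediction and the structural metrics
(`python examples/hydrophobic_collapse.py`, etc.).

A thin CLI wraps the same library calls:

```
crowdfold fold --sequence AAAAAAAAAAAA --ss HHHHHHHHHHHH --out helix.traj
crowdfold crowd --sequence LSLSLSLSLSLSLSLSLSLS --ss CCCCCCCCCCCCCCCCCCCC \
    --fraction 0.0 --fraction 0.5 --replicates 3 --out-dir sweep/
crowdfold analyze --traj sweep/protein_f0.50_r0.traj.gz \
    --native-pdb native.pdb --out-dir metrics/
```

## Scope notes

Secondary-structure prediction and external model-quality scoring are
consumed as inputs (psipred `.ss2`/`.horiz` files; a pluggable scorer
hook), not reimplemented; a built-in geometric assigner can derive
three-state secondary structure from a native Cα trace when no
assignment file is available.  See `docs/methods.md` for the model's
assumptions, parameter choices and limitations.
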