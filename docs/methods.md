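# Methods

## Model

`crowdfold` implements a coarse-grained protein model driven by
Langevin dynamics.  Every residue contributes a backbone bead (Cα) and,
except glycine, a side-chain bead at the side-chain centroid; glycine's
centroid coincides with its Cα in an all-atom model, so it carries no
extra bead.  All protein beads share the same mass (1 base unit).
Units: lengths in Å, time in iterations, rates per iteration; `dt` is
1 iteration.

Per iteration and per particle the update is semi-implicit
(velocity first):

    v ← v·(1 − γ·A·dt/m) + (F/m)·dt + Σ kicks·(kick_speed/m)
    |v| clamped at speed_cap;  x ← x + v·dt

where `A` is the particle's accessible surface area.  The ribosome
particle is immobile (infinite-mass contract); the exit-point particle
carries ribosome-scale mass (1e6) so the tether approximates the
ribosome's inertia.  The per-step drag factor `γ·A·dt/m` is clamped at
0.95 — a numerical guard that is inactive at the default parameters
for all protein beads.

### Force field

All conformational preferences are springs (`k(d − L0)` along the
separation):

| term | pairs | rest length | stiffness (default) |
|------|-------|-------------|---------------------|
| cov  | consecutive backbones; backbone–own side chain | 3.8 Å; per-residue centroid distance | 0.5 |
| bb   | backbone pairs at separations 2, 3 | from ideal helix/strand geometry (below) | 0.08 |
| sc   | side chain – flanking backbones | √(3.8² + centroid²) | 0.05 |
| tether | newest backbone – exit point; exit point – container centre | 3.8 Å; 0 | 0.2 |
| boundary | container overrun / ribosome penetration | — | 1.0 |

Backbone rest lengths for helix pairs come from the ideal α-helix
(rise 1.5 Å/residue, twist 100°, radius fixed by the 3.8 Å consecutive
distance): 5.40 Å at separation 2, 5.04 Å at separation 3.  Strand
pairs use an ideal pleated strand (rise 3.3 Å/residue, lateral offset
fixed by the 3.8 Å bond): 6.6 Å and 10.08 Å.  Mixed and coil pairs use
soft coil restraints (5.9 Å, 7.0 Å) at 15% of the bb stiffness, so
coil regions stay flexible.

Steric repulsion is a linear soft-core ramp from `max_repulsion` at
zero separation to zero at the contact distance `r_i + r_j` (clash
radii: backbone 2.0 Å, side chain 2.2 Å, crowder 15 Å).  A
user-supplied tabulated distance profile can replace the ramp (exact
in the reference engine; the fast kernel approximates a profile by a
ramp scaled to its peak).  Covalently bonded pairs are excluded from
the steric term.  Crowder-involving pairs default to `max_repulsion`
3.0: crowders stand for compact folded domains, whose cores are
stiffer than a single bead's soft clash envelope — and a rigid cage is
what makes extreme crowding trap conformations (see Calibration).

Hydrogen bonding acts between backbone beads at sequence separation
≥ 3.  Virtual H/O sites are placed at ±0.5·3.8 Å along the local chain
bisector at each backbone bead (terminal residues, lacking two
neighbours, carry no sites).  If the closest pair of virtual sites of
two backbones comes within 3.0 Å, a constant-magnitude attraction
(0.1) acts along the site axis on both backbone beads.  This term is
gated and of fixed magnitude, hence not the gradient of a smooth
potential; the spring and steric terms are, and are verified against
finite differences.

### Solvent

Exposure is estimated by casting 32 quasi-uniform rays (Fibonacci
sphere — deterministic, so trajectories are seed-reproducible) from
each bead and testing each direction against the angular caps of
neighbouring solvent spheres.  The neighbour cutoff (30 Å) applies to
the occluder's *surface* (centre distance minus radius); applying it
to centres would exempt exactly the largest occluders (crowders, the
ribosome).  Solvent radii: backbone 2.0 Å; side chains
1.6 + 0.17 × (heavy-atom count) Å, shipped as a configurable table.

Drag is `−γ · A · v` with γ = 0.004 per Å² per iteration.  Kicks
arrive Poisson with mean `kick_rate · A` (kick_rate = 0.004 /Å²/iter),
each with speed 0.3 Å/iter from a uniformly drawn source direction;
blocked directions are discarded, not resampled, so crowded beads are
kicked less.  Hydrophobic side-chain beads (Kyte–Doolittle > 0:
A, C, F, I, L, M, V) use 4× the rate.  Whether drag scales with
exposed area or exposed fraction is a free choice; area was chosen to
match the per-Å² scaling of the kick rate.

### The simulated cell

Container: sphere of radius 50 Å (soft wall, stiffness 1.0, engaging
when a bead's surface passes the wall).  Ribosome: sphere of radius
100 Å centred 100 Å below the container centre, so its surface passes
through the centre, where the exit point sits tethered.  Synthesis
adds residue k's beads at the exit point (offset 0.5 Å outward to
avoid coincident coordinates) at iteration (k−1)·rate, rate = 1000
iterations/residue; the new backbone is tethered, the previous tether
released, and the final tether is released one period after the last
residue, so the chain is complete and free after `l·rate` iterations.

Crowders: spheres of diameter 30 Å and mass 150, the excluded volume
of a ~75-residue protein.  The crowding level is
`n · crowder_volume / available_volume`, where the available volume is
the container minus the container∩ribosome lens (closed form; a config
flag switches to the whole container volume).  Placement constraints:
centre within `container_radius − crowder_radius`, centre outside the
ribosome sphere, pairwise separation ≥ one diameter.  Full-body
ribosome exclusion is geometrically infeasible at 50% (the feasible
centre region is a small cap holding at most ~8 centres 30 Å apart,
versus the 11 crowders 50% requires), so the centre rule is used and
the soft boundary force resolves the residual surface overlap during
dynamics.  Dart-throwing placement jams near the random-sequential-
adsorption limit (~38%), well below 50%, so placement falls back to
randomly oriented FCC-lattice subsets and then to an
overlap-relaxation packer.  Before synthesis begins the crowder bath
alone is integrated for 5000 iterations so the chain emerges into a
settled cell.

### Engines and determinism

The production integrator is a numba kernel over flat arrays; a plain
numpy reference implements the same arithmetic one step at a time.
With the stochastic terms disabled the two agree to 1e-9 over hundreds
of steps (tested); with kicks enabled each engine is bit-reproducible
given its seed, but the two draw from different random generators and
are not cross-comparable.  Chunk seeds are derived from the run seed
via `numpy.random.default_rng`, and exposure caps are rebuilt at every
chunk boundary and every `exposure_interval` steps.

## Analysis metrics

* **TM score** — fixed sequence-order correspondence;
  `d0 = 1.24(L−15)^⅓ − 1.8` clamped at 0.5 from below (0.5 outright
  for L ≤ 15).  Superpositions are seeded from contiguous fragments of
  lengths L, L/2 and 4, extended by iterating inclusion of residues
  within d0, and polished by distance-weighted re-superposition.
  Exactness is claimed against the in-repo dense grid oracle on small
  instances, not against external programs.
* **Alignable fraction** — greedy MaxSub-style seed-and-extend with a
  5 Å cutoff; returns the largest self-consistent subset over all
  seeds, as a fraction of L.
* **Relative Rg** — backbone radius of gyration over the native's.
* **Fixation index** — superposition-free: two samples are similar
  when the mean absolute difference of all pairwise (i<j) internal
  distances is below 4 Å; the index is the earliest sample similar to
  every later one (the last sample qualifies vacuously).
* **Native-like time** — percentage of samples with TM > 0.3.
* **Contact maps** — backbone trace smoothed by a centred 9-residue
  moving average (truncated at the termini); cutoff 8 Å when both
  residues are strand, 11 Å otherwise; pairs inside the same maximal
  helix/strand run (and the diagonal) are ineligible.
* **Percentiles** — linear interpolation between order statistics.

## Prediction protocol

Per trajectory: co-translational synthesis (uncrowded, unbounded
scene), `6000·l + 400000` iterations, 40 samples at equal 10,000-
iteration intervals after iteration `6000·l`; 150 trajectories with
seeds `base_seed + k` give the 6000-structure pool.  Ranking is by
consensus-contact-map similarity: per eligible pair, `+mean` when the
structure has the contact, `−mean` when it lacks it (the functional
form is the natural signed realisation of reward/penalise; alternative
weightings can be plugged in).  The shortlist (top 20) may be rescored
by any callable scorer — the hook where an external model-quality
network would sit; the default keeps the consensus score.  Diversity:
while any two of the current top five are very similar (≥ 90% of
residues within 7 Å of their counterparts after whole-structure
optimal superposition — the per-residue-deviation reading of the
criterion), the lower-scoring one is dropped and the next candidate
promoted, until the top five are diverse or candidates run out; ties
break toward earlier pool provenance.

## Calibration

The model's functional forms are fixed, but its constants are free
parameters of this package.  They were calibrated, once, so the model
exhibits its defining qualitative behaviours, and then frozen:

* Stiffnesses and `dt = 1` keep the stiffest spring well inside the
  stability region of the semi-implicit update; the 1 Å/iteration
  speed cap is a stability device, not physics.
* `kick_rate = 0.004`, `kick_speed = 0.3`,
  `hydrophobic_multiplier = 4`: enough agitation for a free 20-mer to
  collapse within ~5×10⁴ iterations, with clear preferential burial of
  hydrophobic side chains (10/10 seeds on the alternating Leu/Ser
  toy).  A multiplier of 2 produces burial too weak to separate from
  noise at this chain length.
* `k_boundary = 1.0`, crowder `max_repulsion = 3.0`, and 5000
  iterations of crowder pre-equilibration: the cage at 50% excluded
  volume must be rigid and settled.  With a mushy wall and soft
  crowders, the crowders drift throughout the run and continuously
  jostle the trapped chain, which *delays* fixation instead of
  producing the early trapping characteristic of extreme crowding.

## Study configuration and scale

The desk-scale study runs use a toy 40-mer (alternating Leu/Ser,
helix–loop–helix secondary structure) at 0% versus 50% excluded
volume, 10 seeds per level, 10⁵ post-synthesis iterations sampled
every 10³, with exposure recomputed every 4 steps (the package's study
configuration; per-step recomputation is the default and changes no
qualitative outcome).  The full-scale design the bookkeeping code
describes — 12 proteins × 100 replicates × 10⁶ iterations per crowding
level, and 150-trajectory prediction pools — is what the sampling-plan
functions enumerate; running it is a cluster-scale exercise.

## What the synthetic data does and does not show

The fixture generator provides ideal helices, pleated hairpins,
self-avoiding coils, alternating hydrophobic/hydrophilic sequences and
RMSD-controlled decoy pools.  These exercise every code path with
known ground truth, but they are not real proteins: toy chains have no
specific tertiary contacts, so passing tests demonstrate the model's
mechanisms (collapse, burial, trapping, ranking) rather than
predictive accuracy on natural sequences.  Real-protein benchmarking
requires native structures and secondary-structure predictions from
external tools, which the I/O layer accepts but the test suite does
not depend on.

## Degenerate inputs and numerical choices

Coincident spring endpoints with positive rest length have no defined
direction: the force is zero and a warning is logged once.  Collinear
point sets are rejected by superposition.  A non-finite coordinate
aborts integration with the particle index and per-term force
breakdown.  Trajectory files are self-describing text (optionally
gzipped); a converter writes multi-MODEL PDB with CA and CEN records.

## Known limitations

* Distance-only bb springs cannot encode chirality: left- and
  right-handed helices satisfy them equally, which caps helix TM
  scores on short chains.
* The steric ramp is a declared stand-in for a clash-probability
  profile derived from structural statistics; the table format accepts
  such a profile.
* Solvent radii are heuristic (heavy-atom-count scaling), not
  optimised against decoy sets.
* Homogeneous spherical crowders only; no attractive protein–crowder
  chemistry, no electrostatics, no thermostat.
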