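"""Coarse-grained protein representation: two particles per residue.

Each residue contributes a backbone bead at the C-alpha position plus a
side-chain bead at the side-chain centroid; glycine, whose centroid
coincides with its C-alpha in an all-atom model, carries no side-chain
bead.  The conformational preferences of the chain are encoded entirely
as a network of linear springs:

``cov``
    stiff springs between covalently bonded beads — consecutive
    backbone beads, and each backbone bead to its own side-chain bead.
``bb``
    springs between backbone beads at sequence separations 2 and 3
    whose rest lengths depend on the secondary-structure state of the
    two residues (helix / strand / coil), derived from ideal helix and
    strand geometry.
``sc``
    springs from a side-chain bead to the backbone beads of the
    flanking residues, orienting the side chain relative to the chain.
``tether`` / ``boundary``
    machinery springs used by the simulated cell (ribosome exit tether,
    containment restraints).

Units throughout the package: lengths in Angstrom, time in iterations,
mass in multiples of the base bead mass (all protein beads have the
same mass, 1); every rate constant is per iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "Role",
    "Residue",
    "Particle",
    "Spring",
    "ProteinChain",
    "ForceFieldParams",
    "LangevinParams",
    "ParticleSystem",
    "build_chain",
    "default_params",
    "default_force_field",
    "default_langevin",
    "ideal_helix_ca_distance",
    "ideal_strand_ca_distance",
    "AA_ALPHABET",
    "KYTE_DOOLITTLE",
    "HYDROPHOBIC_RESIDUES",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# Kyte-Doolittle hydropathy; residues with positive values carry the
# hydrophobic flag that biases solvent kicks toward burial.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

HYDROPHOBIC_RESIDUES = frozenset(a for a, v in KYTE_DOOLITTLE.items() if v > 0)

# Heavy-atom counts of the side chain (used to scale solvent radii).
SIDECHAIN_HEAVY_ATOMS = {
    "A": 1, "R": 7, "N": 4, "D": 4, "C": 2, "Q": 5, "E": 5, "G": 0,
    "H": 6, "I": 4, "L": 4, "K": 5, "M": 4, "F": 7, "P": 3, "S": 2,
    "T": 3, "W": 10, "Y": 8, "V": 3,
}

# Mean C-alpha to side-chain-centroid distances (Angstrom), typical
# values for each residue type; glycine has no centroid bead.
CA_CENTROID_DISTANCE = {
    "A": 1.53, "R": 4.10, "N": 2.47, "D": 2.44, "C": 2.07,
    "Q": 3.09, "E": 3.11, "G": 0.00, "H": 3.16, "I": 2.31,
    "L": 2.60, "K": 3.50, "M": 2.95, "F": 3.41, "P": 1.88,
    "S": 1.90, "T": 1.93, "W": 3.87, "Y": 3.84, "V": 1.97,
}

SS_STATES = "HEC"

CA_CA_DISTANCE = 3.8  # consecutive C-alpha distance, Angstrom

HELIX_RISE = 1.5          # Angstrom per residue along the helix axis
HELIX_TWIST = 100.0       # degrees per residue
STRAND_RISE = 3.3         # Angstrom per residue along the strand axis


class Role(IntEnum):
    """Particle roles; integer codes are shared with the fast kernel."""

    BACKBONE = 0
    SIDECHAIN = 1
    CROWDER = 2
    RIBOSOME = 3
    EXIT_POINT = 4


def ideal_helix_ca_distance(separation: int) -> float:
    """C-alpha distance at a given sequence separation on an ideal
    alpha helix (rise 1.5 A, twist 100 deg, consecutive distance 3.8 A)."""
    twist = math.radians(HELIX_TWIST)
    # radius chosen so that the separation-1 chord equals 3.8 A
    radius = math.sqrt(CA_CA_DISTANCE**2 - HELIX_RISE**2) / (2.0 * math.sin(twist / 2.0))
    rise = separation * HELIX_RISE
    chord = 2.0 * radius * math.sin(separation * twist / 2.0)
    return math.hypot(rise, chord)


def ideal_strand_ca_distance(separation: int) -> float:
    """C-alpha distance at a given separation on an ideal pleated
    strand (rise 3.3 A per residue, alternating lateral offset chosen
    so consecutive C-alphas sit 3.8 A apart)."""
    offset = math.sqrt(CA_CA_DISTANCE**2 - STRAND_RISE**2)  # peak-to-peak
    rise = separation * STRAND_RISE
    lateral = 0.0 if separation % 2 == 0 else offset
    return math.hypot(rise, lateral)


# Coil / mixed secondary structure: soft restraints near random-coil
# average distances (see docs/methods.md).
COIL_BB_REST = {2: 5.9, 3: 7.0}


def _default_bb_rest_lengths() -> dict[tuple[str, int], float]:
    table: dict[tuple[str, int], float] = {}
    for a in SS_STATES:
        for b in SS_STATES:
            for sep in (2, 3):
                if a == b == "H":
                    d = ideal_helix_ca_distance(sep)
                elif a == b == "E":
                    d = ideal_strand_ca_distance(sep)
                else:
                    d = COIL_BB_REST[sep]
                table[(a + b, sep)] = d
    return table


# Steric (clash) radii by role, used by the default van der Waals
# contact rule contact = r_i + r_j.
DEFAULT_VDW_RADII = {
    "backbone": 2.0,
    "sidechain": 2.2,
    "crowder": 15.0,
    "exit_point": 2.0,
}


# crowders model compact folded domains: their steric core is stiffer
# than a single coarse bead's soft clash envelope
CROWDER_MAX_REPULSION = 3.0


def _default_vdw_table() -> dict[tuple[str, str], tuple[float, float]]:
    types = sorted(DEFAULT_VDW_RADII)
    table = {}
    for i, a in enumerate(types):
        for b in types[i:]:
            contact = DEFAULT_VDW_RADII[a] + DEFAULT_VDW_RADII[b]
            max_rep = CROWDER_MAX_REPULSION if "crowder" in (a, b) else 1.0
            table[(a, b)] = (contact, max_rep)
    return table


@dataclass(frozen=True)
class Residue:
    index: int          # 1-based
    aa: str             # one-letter code
    ss: str             # 'H', 'E' or 'C'
    hydrophobic: bool

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"residue index must be >= 1, got {self.index}")
        if self.aa not in AA_ALPHABET:
            raise ValueError(f"unknown amino-acid letter {self.aa!r}")
        if self.ss not in SS_STATES:
            raise ValueError(f"secondary structure must be H/E/C, got {self.ss!r}")


@dataclass
class Particle:
    id: int
    role: Role
    residue_index: Optional[int]    # 1-based, None for non-protein particles
    position: np.ndarray            # (3,) Angstrom
    velocity: np.ndarray            # (3,) Angstrom / iteration
    mass: float                     # base-particle units
    solvent_radius: float           # Angstrom
    hydrophobic: bool = False

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("particle mass must be positive")
        if self.solvent_radius < 0:
            raise ValueError("solvent radius must be non-negative")
        if self.role in (Role.BACKBONE, Role.SIDECHAIN) and self.residue_index is None:
            raise ValueError("protein particles need a residue index")
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)


@dataclass(frozen=True)
class Spring:
    i: int
    j: int
    rest_length: float
    stiffness: float
    category: str   # cov | bb | sc | tether | boundary

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("spring endpoints must differ")
        if self.rest_length < 0 or self.stiffness < 0:
            raise ValueError("spring rest length and stiffness must be >= 0")


@dataclass
class ProteinChain:
    """Sequence, secondary structure and particle/spring topology."""

    sequence: str
    ss: str
    residues: list[Residue]
    particle_ids: list[tuple[int, Optional[int]]]  # (backbone_id, sidechain_id)
    springs: list[Spring]
    particles: list[Particle] = field(default_factory=list)
    synthesized_count: int = 0

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def backbone_ids(self) -> list[int]:
        return [b for b, _ in self.particle_ids]

    @property
    def sidechain_ids(self) -> list[Optional[int]]:
        return [s for _, s in self.particle_ids]

    def n_particles(self) -> int:
        return len(self.particles)


@dataclass
class ForceFieldParams:
    """Spring stiffnesses, rest lengths and steric/h-bond parameters.

    All defaults are package choices (the model's published description
    gives the functional forms but not the constants); every value is
    overridable through the YAML config.
    """

    k_cov: float = 0.5
    k_bb: float = 0.08
    k_sc: float = 0.05
    k_tether: float = 0.2
    k_boundary: float = 1.0
    bb_coil_scale: float = 0.15     # stiffness scale for coil/mixed bb springs
    cov_ca_ca: float = CA_CA_DISTANCE
    cov_ca_centroid: dict[str, float] = field(
        default_factory=lambda: dict(CA_CENTROID_DISTANCE))
    bb_rest_lengths: dict[tuple[str, int], float] = field(
        default_factory=_default_bb_rest_lengths)
    vdw_table: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=_default_vdw_table)
    vdw_radii: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VDW_RADII))
    hb_threshold: float = 3.0
    hb_strength: float = 0.1
    hb_min_separation: int = 3

    def __post_init__(self) -> None:
        for name in ("k_cov", "k_bb", "k_sc", "k_tether", "k_boundary",
                     "cov_ca_ca", "hb_threshold", "hb_strength"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for a in SS_STATES:
            for b in SS_STATES:
                for sep in (2, 3):
                    if (a + b, sep) not in self.bb_rest_lengths:
                        raise ValueError(
                            f"bb_rest_lengths missing entry ({a + b}, {sep})")


@dataclass
class LangevinParams:
    """Parameters of the Langevin solvent model and the integrator.

    gamma
        drag per unit exposed area per iteration; the drag force on a
        particle is ``-gamma * accessible_area * velocity``.
    kick_speed / kick_rate
        every solvent kick carries the same speed; kicks arrive with a
        Poisson rate of ``kick_rate`` per square Angstrom of accessible
        surface per iteration, multiplied by ``hydrophobic_multiplier``
        for hydrophobic side-chain beads.
    exposure_rays
        number of quasi-uniform directions used to estimate the exposed
        surface fraction of each bead.
    speed_cap
        hard clamp on particle speed, a numerical stability device.
    """

    gamma: float = 0.004
    kick_speed: float = 0.3
    kick_rate: float = 0.004
    hydrophobic_multiplier: float = 4.0
    dt: float = 1.0
    exposure_rays: int = 32
    neighbor_cutoff: float = 30.0
    speed_cap: float = 1.0
    seed: int = 0
    exposure_interval: int = 1
    backbone_solvent_radius: float = 2.0
    sidechain_radius_base: float = 1.6
    sidechain_radius_per_atom: float = 0.17
    # optional per-type override table ('backbone' or one-letter codes),
    # e.g. loaded from a radii file via crowdfold.io.read_radii_table
    radii_table: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.gamma < 0 or self.kick_rate < 0:
            raise ValueError("gamma and kick_rate must be >= 0")
        if self.hydrophobic_multiplier < 1:
            raise ValueError("hydrophobic_multiplier must be >= 1")
        if self.exposure_rays < 1:
            raise ValueError("exposure_rays must be >= 1")
        if self.exposure_interval < 1:
            raise ValueError("exposure_interval must be >= 1")

    def sidechain_solvent_radius(self, aa: str) -> float:
        if self.radii_table and aa in self.radii_table:
            return float(self.radii_table[aa])
        n = SIDECHAIN_HEAVY_ATOMS[aa]
        return self.sidechain_radius_base + self.sidechain_radius_per_atom * n

    def effective_backbone_radius(self) -> float:
        if self.radii_table and "backbone" in self.radii_table:
            return float(self.radii_table["backbone"])
        return self.backbone_solvent_radius


def default_force_field() -> ForceFieldParams:
    return ForceFieldParams()


def default_langevin() -> LangevinParams:
    return LangevinParams()


def default_params() -> tuple[ForceFieldParams, LangevinParams]:
    """The documented default parameter set (all configurable)."""
    return default_force_field(), default_langevin()


def build_chain(sequence: str, ss: str,
                ff: Optional[ForceFieldParams] = None,
                lp: Optional[LangevinParams] = None) -> ProteinChain:
    """Construct the particle/spring topology for a sequence.

    One backbone bead per residue, one side-chain bead per non-glycine
    residue; springs follow the cov/bb/sc rules described in the module
    docstring.  Positions are initialised to zero — the integrator or
    the synthesis machinery places the beads.
    """
    if ff is None:
        ff = default_force_field()
    if lp is None:
        lp = default_langevin()
    sequence = sequence.upper()
    ss = ss.upper()
    if len(sequence) != len(ss):
        raise ValueError(
            f"sequence length {len(sequence)} != secondary structure length {len(ss)}")
    if len(sequence) < 1:
        raise ValueError("sequence must contain at least one residue")
    for pos, a in enumerate(sequence, start=1):
        if a not in AA_ALPHABET:
            raise ValueError(
                f"unknown amino-acid letter {a!r} at position {pos}")
    for pos, s in enumerate(ss, start=1):
        if s not in SS_STATES:
            raise ValueError(
                f"secondary structure state {s!r} at position {pos}; use H, E or C")

    residues = [
        Residue(index=i, aa=a, ss=s, hydrophobic=a in HYDROPHOBIC_RESIDUES)
        for i, (a, s) in enumerate(zip(sequence, ss), start=1)
    ]

    particles: list[Particle] = []
    particle_ids: list[tuple[int, Optional[int]]] = []

    def _new_particle(role: Role, res: Residue, radius: float) -> int:
        pid = len(particles)
        particles.append(Particle(
            id=pid, role=role, residue_index=res.index,
            position=np.zeros(3), velocity=np.zeros(3),
            mass=1.0, solvent_radius=radius,
            hydrophobic=(role is Role.SIDECHAIN and res.hydrophobic)))
        return pid

    for res in residues:
        b = _new_particle(Role.BACKBONE, res, lp.effective_backbone_radius())
        s = None
        if res.aa != "G":
            s = _new_particle(Role.SIDECHAIN, res,
                              lp.sidechain_solvent_radius(res.aa))
        particle_ids.append((b, s))

    springs: list[Spring] = []
    n = len(residues)

    # cov: consecutive backbones and backbone <-> own side chain
    for i in range(n - 1):
        springs.append(Spring(particle_ids[i][0], particle_ids[i + 1][0],
                              ff.cov_ca_ca, ff.k_cov, "cov"))
    for i, res in enumerate(residues):
        sc = particle_ids[i][1]
        if sc is not None:
            springs.append(Spring(particle_ids[i][0], sc,
                                  ff.cov_ca_centroid[res.aa], ff.k_cov, "cov"))

    # bb: separations 2 and 3 with ss-dependent rest lengths
    for sep in (2, 3):
        for i in range(n - sep):
            ss_pair = residues[i].ss + residues[i + sep].ss
            rest = ff.bb_rest_lengths[(ss_pair, sep)]
            k = ff.k_bb
            if not (ss_pair in ("HH", "EE")):
                k *= ff.bb_coil_scale
            springs.append(Spring(particle_ids[i][0], particle_ids[i + sep][0],
                                  rest, k, "bb"))

    # sc: side chain to flanking backbones
    for i, res in enumerate(residues):
        sc = particle_ids[i][1]
        if sc is None:
            continue
        rest = math.hypot(ff.cov_ca_ca, ff.cov_ca_centroid[res.aa])
        for j in (i - 1, i + 1):
            if 0 <= j < n:
                springs.append(Spring(sc, particle_ids[j][0], rest, ff.k_sc, "sc"))

    return ProteinChain(sequence=sequence, ss=ss, residues=residues,
                        particle_ids=particle_ids, springs=springs,
                        particles=particles, synthesized_count=0)


@dataclass
class ParticleSystem:
    """Structure-of-arrays container for all particles in a simulation.

    ``active`` marks particles currently present (unsynthesized residues
    start inactive); ``movable`` is False only for the ribosome, which is
    held immobile (infinite-mass contract).
    """

    pos: np.ndarray            # (n, 3) float64
    vel: np.ndarray            # (n, 3) float64
    mass: np.ndarray           # (n,)
    solvent_radius: np.ndarray  # (n,)
    role: np.ndarray           # (n,) int8 (Role codes)
    residue_index: np.ndarray  # (n,) int32, -1 for non-protein
    hydrophobic: np.ndarray    # (n,) bool
    movable: np.ndarray        # (n,) bool
    active: np.ndarray         # (n,) bool

    @property
    def n(self) -> int:
        return self.pos.shape[0]

    @classmethod
    def from_particles(cls, particles: Iterable[Particle]) -> "ParticleSystem":
        plist = list(particles)
        n = len(plist)
        sys = cls(
            pos=np.zeros((n, 3)), vel=np.zeros((n, 3)),
            mass=np.ones(n), solvent_radius=np.zeros(n),
            role=np.zeros(n, dtype=np.int8),
            residue_index=np.full(n, -1, dtype=np.int32),
            hydrophobic=np.zeros(n, dtype=bool),
            movable=np.ones(n, dtype=bool),
            active=np.ones(n, dtype=bool),
        )
        for k, p in enumerate(plist):
            sys.pos[k] = p.position
            sys.vel[k] = p.velocity
            sys.mass[k] = p.mass
            sys.solvent_radius[k] = p.solvent_radius
            sys.role[k] = int(p.role)
            sys.residue_index[k] = -1 if p.residue_index is None else p.residue_index
            sys.hydrophobic[k] = p.hydrophobic
            sys.movable[k] = p.role != Role.RIBOSOME
        return sys

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            pos=self.pos.copy(), vel=self.vel.copy(), mass=self.mass.copy(),
            solvent_radius=self.solvent_radius.copy(), role=self.role.copy(),
            residue_index=self.residue_index.copy(),
            hydrophobic=self.hydrophobic.copy(), movable=self.movable.copy(),
            active=self.active.copy())


def role_name(code: int) -> str:
    return Role(code).name.lower()


def extended_positions(chain: ProteinChain, ff: ForceFieldParams) -> np.ndarray:
    """Starting coordinates for a free (non-synthesized) chain: a
    gently zig-zagged extended backbone with side-chain beads offset
    laterally."""
    n = len(chain.particles)
    pos = np.zeros((n, 3))
    for i, res in enumerate(chain.residues):
        bb, sc = chain.particle_ids[i]
        zig = 0.9 * (-1.0) ** i
        pos[bb] = (zig, 0.0, i * 3.6)
        if sc is not None:
            pos[sc] = (zig + ff.cov_ca_centroid[res.aa], 0.8, i * 3.6)
    return pos


def make_system(chain: ProteinChain,
                positions: Optional[np.ndarray] = None,
                ff: Optional[ForceFieldParams] = None) -> ParticleSystem:
    """ParticleSystem for a free chain (no cell machinery), fully
    synthesized, starting from ``positions`` (default: extended)."""
    system = ParticleSystem.from_particles(chain.particles)
    if positions is None:
        positions = extended_positions(chain, ff or ForceFieldParams())
    system.pos[:] = positions
    chain.synthesized_count = len(chain)
    return system
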