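"""Readers, writers, fixtures and configuration.

Structures move through standard formats: FASTA for sequences
(Biopython), PDB for coordinates (C-alpha records plus ``CEN``
pseudo-atoms for side-chain centroids; multi-MODEL for trajectories),
psipred ``.ss2``/``.horiz`` or a plain H/E/C string for secondary
structure, YAML for configuration.  A deterministic fixture generator
provides ideal helices, beta hairpins, self-avoiding coils, toy
sequences and decoy pools so that every part of the package is
testable without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1

from .model_core import (AA_ALPHABET, CA_CA_DISTANCE, HELIX_RISE, HELIX_TWIST,
                         STRAND_RISE, ForceFieldParams, LangevinParams,
                         default_params)

__all__ = ["NativeStructure", "read_pdb", "write_pdb", "read_fasta",
           "read_ss", "assign_ss_geometric", "make_fixture",
           "load_config", "save_config", "effective_config"]

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass
class NativeStructure:
    """C-alpha trace plus side-chain centroids of a reference structure."""

    sequence: str
    ca: np.ndarray             # (L, 3)
    centroids: np.ndarray      # (L, 3); equals ca for glycine
    ss: Optional[str] = None
    name: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


def read_pdb(path, chain_id: Optional[str] = None) -> NativeStructure:
    """Extract a single chain's C-alpha trace and side-chain centroids.

    Only the first model is read; HETATM records, waters and altloc
    variants beyond 'A' are skipped; residues are taken in file order
    (insertion codes included).  A residue without a C-alpha atom is an
    error naming the residue.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    chains = {c.id: c for c in model.get_chains()}
    if chain_id is None:
        chain_id = next(iter(chains))
    if chain_id not in chains:
        raise ValueError(f"{path}: no chain {chain_id!r} "
                         f"(available: {sorted(chains)})")
    seq = []
    cas = []
    cens = []
    missing = []
    for res in chains[chain_id]:
        if res.id[0] != " ":     # skip HETATM / water
            continue
        try:
            aa = seq1(res.get_resname())
        except Exception:
            aa = "X"
        if aa == "X" or aa not in AA_ALPHABET:
            continue
        atoms = [a for a in res
                 if a.get_altloc() in (" ", "A") and a.element != "H"]
        ca = next((a for a in atoms if a.get_name() == "CA"), None)
        if ca is None:
            missing.append(f"{res.get_resname()}{res.id[1]}")
            continue
        side = [a.get_coord() for a in atoms
                if a.get_name() not in BACKBONE_ATOMS]
        seq.append(aa)
        cas.append(ca.get_coord())
        cens.append(np.mean(side, axis=0) if side else ca.get_coord())
    if missing:
        raise ValueError(f"{path}: residues without C-alpha atoms: "
                         f"{', '.join(missing)}")
    if not seq:
        raise ValueError(f"{path}: chain {chain_id!r} contains no "
                         "standard amino acids")
    return NativeStructure(sequence="".join(seq),
                           ca=np.asarray(cas, dtype=float),
                           centroids=np.asarray(cens, dtype=float),
                           name=f"{Path(path).stem}:{chain_id}")


_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def write_pdb(conformations, path, sequence: Optional[str] = None,
              centroids=None, remarks: tuple = ()) -> None:
    """Write one or more conformations as (multi-MODEL) PDB.

    Backbone beads become CA records; side-chain centroids (when
    given) become ``CEN`` pseudo-atoms on the same residue.
    Coordinates use the standard fixed %8.3f columns.
    """
    confs = np.asarray(conformations, dtype=float)
    if confs.ndim == 2:
        confs = confs[None]
    if confs.ndim != 3 or confs.shape[0] < 1:
        raise ValueError("need at least one (L, 3) conformation")
    L = confs.shape[1]
    seq = sequence or "A" * L
    cens = None
    if centroids is not None:
        cens = np.asarray(centroids, dtype=float)
        if cens.ndim == 2:
            cens = cens[None]
    multi = confs.shape[0] > 1
    with open(path, "w") as fh:
        for rem in remarks:
            fh.write(f"REMARK   6 {rem}\n")
        for m, conf in enumerate(confs, start=1):
            if multi:
                fh.write(f"MODEL     {m:>4d}\n")
            serial = 1
            for i in range(L):
                resn = _AA3.get(seq[i], "ALA")
                x, y, z = conf[i]
                fh.write(f"ATOM  {serial:>5d}  CA  {resn} A{i + 1:>4d}    "
                         f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n")
                serial += 1
                if cens is not None and seq[i] != "G":
                    cx, cy, cz = cens[m - 1, i]
                    fh.write(f"ATOM  {serial:>5d}  CEN {resn} A{i + 1:>4d}    "
                             f"{cx:8.3f}{cy:8.3f}{cz:8.3f}  1.00  0.00           C\n")
                    serial += 1
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def read_fasta(path) -> str:
    """Sequence of the first FASTA record."""
    from Bio import SeqIO
    rec = next(SeqIO.parse(str(path), "fasta"), None)
    if rec is None:
        raise ValueError(f"{path}: no FASTA records found")
    return str(rec.seq).upper()


def read_ss(source, sequence: Optional[str] = None) -> str:
    """Three-state secondary structure from a plain H/E/C string, a
    psipred ``.ss2`` file or a psipred ``.horiz`` file."""
    text = None
    src = str(source)
    if isinstance(source, Path):
        text = source.read_text()
    elif "\n" not in src and len(src) < 4096 and Path(src).exists():
        text = Path(src).read_text()
    if text is None:
        candidate = src.strip().upper()
        if candidate and all(c in "HEC" for c in candidate):
            ss = candidate
            if sequence is not None and len(ss) != len(sequence):
                raise ValueError(
                    f"secondary structure length {len(ss)} != "
                    f"sequence length {len(sequence)}")
            return ss
        raise ValueError(f"cannot interpret secondary structure source "
                         f"{src[:50]!r}")
    lines = text.splitlines()
    states = []
    if any(l.strip().startswith("Pred:") for l in lines):    # .horiz
        for line in lines:
            if line.strip().startswith("Pred:"):
                states.append(line.split("Pred:", 1)[1].strip())
        ss = "".join(states).upper()
    else:                                                    # .ss2
        for ln, line in enumerate(lines, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) < 3:
                raise ValueError(f"line {ln}: malformed .ss2 record {line!r}")
            states.append(parts[2])
        ss = "".join(states).upper()
    ss = "".join("C" if c not in "HE" else c for c in ss)
    if not ss:
        raise ValueError("no secondary structure states found")
    if sequence is not None and len(ss) != len(sequence):
        raise ValueError(f"secondary structure length {len(ss)} != "
                         f"sequence length {len(sequence)}")
    return ss


def assign_ss_geometric(ca: np.ndarray) -> str:
    """Three-state assignment from C-alpha geometry alone.

    A coarse geometric assigner (a stand-in for a full
    secondary-structure assignment program): residues in runs where the
    i to i+3 distance matches helical geometry (< 6 A) become H;
    residues in locally extended stretches (i to i+2 distance > 6.3 A)
    become E; everything else is coil.
    """
    ca = np.asarray(ca, dtype=float)
    L = len(ca)
    ss = ["C"] * L
    for i in range(L - 3):
        if np.linalg.norm(ca[i + 3] - ca[i]) < 6.0:
            for j in range(i, i + 4):
                ss[j] = "H"
    for i in range(L - 2):
        if ss[i] == "C" and ss[i + 2] == "C" \
                and np.linalg.norm(ca[i + 2] - ca[i]) > 6.3:
            for j in range(i, i + 3):
                if ss[j] == "C":
                    ss[j] = "E"
    return "".join(ss)


# ---------------------------------------------------------------------------
# fixtures

def _helix_coords(length: int) -> np.ndarray:
    twist = math.radians(HELIX_TWIST)
    radius = math.sqrt(CA_CA_DISTANCE**2 - HELIX_RISE**2) / (2 * math.sin(twist / 2))
    k = np.arange(length)
    return np.stack([radius * np.cos(k * twist),
                     radius * np.sin(k * twist),
                     k * HELIX_RISE], axis=1)


def _strand_coords(length: int, x0: float = 0.0, direction: int = 1,
                   z0: float = 0.0) -> np.ndarray:
    offset = math.sqrt(CA_CA_DISTANCE**2 - STRAND_RISE**2) / 2
    k = np.arange(length)
    return np.stack([np.full(length, x0) + offset * (-1.0) ** k,
                     np.zeros(length),
                     z0 + direction * k * STRAND_RISE], axis=1)


def _hairpin_coords(length: int) -> tuple[np.ndarray, str]:
    turn = 4
    arm = (length - turn) // 2
    rest = length - turn - 2 * arm
    s1 = _strand_coords(arm)
    # semicircular turn connecting the strand ends
    pair_dist = 5.0
    t = np.linspace(0, math.pi, turn + 2)[1:-1]
    tz = s1[-1, 2]
    turn_xy = np.stack([pair_dist / 2 - pair_dist / 2 * np.cos(t),
                        np.zeros(turn),
                        tz + 2.5 * np.sin(t)], axis=1)
    s2 = _strand_coords(arm + rest, x0=pair_dist, direction=-1, z0=tz)
    coords = np.vstack([s1, turn_xy, s2])
    ss = "E" * arm + "C" * turn + "E" * (arm + rest)
    return coords, ss


def _self_avoiding_coil(length: int, rng: np.random.Generator,
                        min_dist: float = 3.0) -> np.ndarray:
    for _ in range(200):   # restart budget
        pts = [np.zeros(3)]
        ok = True
        for _ in range(length - 1):
            placed = False
            for _ in range(200):
                u = rng.standard_normal(3)
                u /= np.linalg.norm(u)
                cand = pts[-1] + CA_CA_DISTANCE * u
                d = np.linalg.norm(np.asarray(pts[:-1]) - cand, axis=1) \
                    if len(pts) > 1 else np.array([np.inf])
                if d.min() >= min_dist:
                    pts.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.asarray(pts)
    raise RuntimeError("self-avoiding walk failed to complete")


TOY_PATTERN = "LS"   # alternating hydrophobic / hydrophilic


def make_fixture(kind: str, seed: int = 0, **params):
    """Deterministic test structures and sequences.

    Kinds: ``ideal_helix``, ``beta_hairpin``, ``random_coil``,
    ``toy_sequence``, ``decoy_pool``.  Everything is reproducible from
    (kind, params, seed).
    """
    rng = np.random.default_rng(seed)
    if kind == "ideal_helix":
        L = int(params.get("length", 12))
        ca = _helix_coords(L)
        return NativeStructure(sequence="A" * L, ca=ca, centroids=ca.copy(),
                               ss="H" * L, name=f"ideal_helix_{L}")
    if kind == "beta_hairpin":
        L = int(params.get("length", 12))
        ca, ss = _hairpin_coords(L)
        return NativeStructure(sequence="V" * L, ca=ca, centroids=ca.copy(),
                               ss=ss, name=f"beta_hairpin_{L}")
    if kind == "random_coil":
        L = int(params.get("length", 20))
        ca = _self_avoiding_coil(L, rng)
        return NativeStructure(sequence="A" * L, ca=ca, centroids=ca.copy(),
                               ss="C" * L, name=f"random_coil_{L}")
    if kind == "toy_sequence":
        L = int(params.get("length", 20))
        pattern = params.get("pattern", TOY_PATTERN)
        return (pattern * (L // len(pattern) + 1))[:L]
    if kind == "decoy_pool":
        native = np.asarray(params["native"], dtype=float)
        rmsd_levels = params.get("rmsd_levels", (0.0, 2.0, 5.0))
        per_level = int(params.get("per_level", 3))
        decoys = []
        for level in rmsd_levels:
            for _ in range(per_level):
                noise = rng.standard_normal(native.shape)
                if level > 0:
                    noise *= level / np.sqrt((noise ** 2).sum(axis=1).mean())
                else:
                    noise[:] = 0.0
                decoys.append(native + noise)
        return np.stack(decoys)
    raise ValueError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# parameter tables

def read_vdw_table(path) -> dict:
    """Steric table: whitespace-delimited columns
    ``type_i type_j contact_distance_A max_repulsion``; '#' comments."""
    table = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        s = line.split("#", 1)[0].strip()
        if not s:
            continue
        parts = s.split()
        if len(parts) != 4:
            raise ValueError(f"{path}:{ln}: expected 4 columns, got {s!r}")
        a, b, contact, max_rep = parts
        table[tuple(sorted((a, b)))] = (float(contact), float(max_rep))
    return table


def read_radii_table(path) -> dict:
    """Solvent radii: whitespace-delimited columns
    ``particle_type radius_A`` ('backbone' or one-letter residue codes);
    '#' comments."""
    radii = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        s = line.split("#", 1)[0].strip()
        if not s:
            continue
        parts = s.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected 2 columns, got {s!r}")
        radii[parts[0]] = float(parts[1])
    return radii


# ---------------------------------------------------------------------------
# configuration

def effective_config(ff: ForceFieldParams, lp: LangevinParams) -> dict:
    """YAML-serialisable view of the full parameter set."""
    return {
        "force_field": {
            **{k: getattr(ff, k) for k in
               ("k_cov", "k_bb", "k_sc", "k_tether", "k_boundary",
                "bb_coil_scale", "cov_ca_ca", "hb_threshold", "hb_strength",
                "hb_min_separation")},
            "cov_ca_centroid": dict(ff.cov_ca_centroid),
            "bb_rest_lengths": {
                pair: {str(sep): ff.bb_rest_lengths[(pair, sep)]
                       for sep in (2, 3)}
                for pair in sorted({p for p, _ in ff.bb_rest_lengths})},
            "vdw_radii": dict(ff.vdw_radii),
            "vdw_table": {f"{a}|{b}": list(map(float, np.ravel(v)))
                          for (a, b), v in ff.vdw_table.items()},
        },
        "langevin": {
            **{k: getattr(lp, k) for k in
               ("gamma", "kick_speed", "kick_rate",
                "hydrophobic_multiplier", "dt", "exposure_rays",
                "neighbor_cutoff", "speed_cap", "seed",
                "exposure_interval", "backbone_solvent_radius",
                "sidechain_radius_base", "sidechain_radius_per_atom")},
            "radii_table": lp.radii_table,
        },
    }


def load_config(path) -> tuple[ForceFieldParams, LangevinParams]:
    """Build parameter sets from a YAML file; unspecified keys keep
    their defaults."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    ff, lp = default_params()
    ffc = cfg.get("force_field", {}) or {}
    for k, v in ffc.items():
        if k == "bb_rest_lengths":
            for pair, seps in v.items():
                for sep, val in seps.items():
                    ff.bb_rest_lengths[(pair.upper(), int(sep))] = float(val)
        elif k == "cov_ca_centroid":
            ff.cov_ca_centroid.update({a.upper(): float(x) for a, x in v.items()})
        elif k == "vdw_radii":
            ff.vdw_radii.update({a: float(x) for a, x in v.items()})
        elif k == "vdw_table":
            for key, val in v.items():
                a, b = key.split("|")
                arr = np.asarray(val, dtype=float)
                ff.vdw_table[tuple(sorted((a, b)))] = (
                    tuple(arr) if arr.ndim == 1 and arr.size == 2
                    else arr.reshape(-1, 2))
        elif hasattr(ff, k):
            setattr(ff, k, type(getattr(ff, k))(v))
        else:
            raise ValueError(f"unknown force_field key {k!r}")
    lpc = cfg.get("langevin", {}) or {}
    for k, v in lpc.items():
        if not hasattr(lp, k):
            raise ValueError(f"unknown langevin key {k!r}")
        if k == "radii_table":
            lp.radii_table = None if v is None else {
                str(t): float(r) for t, r in v.items()}
        else:
            setattr(lp, k, type(getattr(lp, k))(v))
    ff.__post_init__()
    lp.__post_init__()
    return ff, lp


def save_config(ff: ForceFieldParams, lp: LangevinParams, path) -> None:
    """Write the effective configuration next to a run's outputs."""
    with open(path, "w") as fh:
        yaml.safe_dump(effective_config(ff, lp), fh, sort_keys=True)
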