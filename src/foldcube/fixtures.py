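"""Synthetic miniature structures with prescribed pair geometry.

Generates small chains whose designated residue pair sits at a chosen
functional-atom distance, solvent shell, secondary structure and sequence
separation — the geometries of well-known motifs (disulphide bridge, zinc
finger, iron-sulfur cluster, salt bridge, close Arg-Arg) — and writes them
as genuine PDB ATOM records plus an annotation file (tabular dialect or a
minimal HSSP residue block), so the whole pipeline can be exercised
without any real structure.  Fixture chains are geometrically valid for
the pipeline's purposes but make no claim of physical realism: spacer
residues are placed far apart so the designated pair is the only pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import geometry
from .constants import (
    AMINO_ACIDS,
    FUNCTIONAL_ATOMS,
    REFERENCE_AREAS,
    SS_CLASSES,
    THREE_TO_ONE,
)
from .model import AtomRecord, ChainModel, ResidueRecord

MOTIFS = ("disulphide", "zinc_finger_like", "iron_sulfur_like",
          "salt_bridge", "arg_arg_close", "repulsive_pair")

_SS_TO_CODE = {"helix": "H", "strand": "E", "turn": "T", "coil": "C"}


@dataclass
class ResidueSpec:
    """Blueprint for one fixture residue."""

    aa_type: str
    chain_id: str
    author_number: int
    ss_class: str
    rel_sa: float
    functional_atoms: dict[str, tuple[float, float, float]]
    ca: tuple[float, float, float] | None = None  # defaults to 1st functional atom

    @property
    def sasa(self) -> float:
        return self.rel_sa / 100.0 * REFERENCE_AREAS[self.aa_type]

    def atom_dict(self) -> dict[str, tuple[float, float, float]]:
        atoms = dict(self.functional_atoms)
        atoms.setdefault("CA", self.ca if self.ca is not None
                         else next(iter(self.functional_atoms.values())))
        return atoms


@dataclass
class ToySpec:
    """Blueprint for one miniature chain."""

    pdb_id: str
    residues: list[ResidueSpec] = field(default_factory=list)


def _functional_positions(aa_type: str, anchor: np.ndarray,
                          away: np.ndarray) -> dict[str, tuple]:
    """Place the residue's functional atoms: the first exactly at
    ``anchor``; a second (if the type has one) 2.2 Å further along
    ``away``, so the minimum pair distance is the anchor separation."""
    names = FUNCTIONAL_ATOMS[aa_type]
    out = {names[0]: tuple(anchor)}
    if len(names) > 1:
        out[names[1]] = tuple(anchor + 2.2 * away)
    return out


def _pair_chain(pdb_id: str, aa1: str, aa2: str, distance: float,
                pair_positions: tuple[int, int], rel_sa: float,
                ss_class: str, n_residues: int = 8,
                chain_id: str = "A") -> ToySpec:
    """A chain whose designated pair (1-based positions) sits at the given
    functional-atom distance and shell; spacer Gly residues are isolated
    (>8 Å apart, different shell) so they contribute no pairs."""
    i, j = pair_positions
    residues: list[ResidueSpec] = []
    a1 = np.array([0.0, 0.0, 0.0])
    a2 = np.array([distance, 0.0, 0.0])
    spacer_sa = 95.0 if rel_sa <= 85.0 else 5.0
    for pos in range(1, n_residues + 1):
        if pos == i or pos == j:
            anchor, away = (a1, np.array([-1.0, 0.0, 0.0])) if pos == i \
                else (a2, np.array([1.0, 0.0, 0.0]))
            aa = aa1 if pos == i else aa2
            residues.append(ResidueSpec(
                aa_type=aa, chain_id=chain_id, author_number=pos,
                ss_class=ss_class, rel_sa=rel_sa,
                functional_atoms=_functional_positions(aa, anchor, away),
                ca=tuple(anchor + np.array([0.0, 1.5, 0.0])),
            ))
        else:
            p = (100.0 + 10.0 * pos, 50.0, 50.0)
            residues.append(ResidueSpec(
                aa_type="GLY", chain_id=chain_id, author_number=pos,
                ss_class="coil", rel_sa=spacer_sa,
                functional_atoms={"CA": p}))
    return ToySpec(pdb_id=pdb_id, residues=residues)


def make_motif_chain(motif: str, seed: int = 0) -> ToySpec:
    """A miniature chain realizing one motif's pair geometry.

    Designated-pair distances are drawn (seeded) strictly inside the
    motif's characteristic distance range:

    ==================  =========  ============  ==========  =====
    motif               residues   distance (Å)  shell (SA)  SD
    ==================  =========  ============  ==========  =====
    disulphide          Cys-Cys    1.80-2.24     <=10 %      >4
    zinc_finger_like    Cys-Cys    3.81-4.24     <=10 %      <=4
    iron_sulfur_like    Cys-Cys    6.76-7.24     <=10 %      <=4
    salt_bridge         Lys-Asp    2.31-3.24     20-30 %     4
    arg_arg_close       Arg-Arg    3.31-3.74     10-20 %     >4
    repulsive_pair      Lys-Lys    12 (no pair)  40-50 %     >4
    ==================  =========  ============  ==========  =====
    """
    rng = np.random.default_rng(seed)
    if motif == "disulphide":
        d = rng.uniform(1.80, 2.24)
        return _pair_chain("0DSB", "CYS", "CYS", d, (1, 7), 5.0, "coil")
    if motif == "zinc_finger_like":
        d = rng.uniform(3.81, 4.24)
        return _pair_chain("0ZNF", "CYS", "CYS", d, (3, 5), 5.0, "strand")
    if motif == "iron_sulfur_like":
        d = rng.uniform(6.76, 7.24)
        return _pair_chain("0FES", "CYS", "CYS", d, (3, 5), 5.0, "coil")
    if motif == "salt_bridge":
        d = rng.uniform(2.31, 3.24)
        return _pair_chain("0SAL", "LYS", "ASP", d, (2, 6), 25.0, "helix")
    if motif == "arg_arg_close":
        d = rng.uniform(3.31, 3.74)
        return _pair_chain("0ARG", "ARG", "ARG", d, (1, 7), 15.0, "coil")
    if motif == "repulsive_pair":
        return _pair_chain("0REP", "LYS", "LYS", 12.0, (1, 7), 45.0, "coil")
    raise ValueError(f"unknown motif {motif!r}; choose from {MOTIFS}")


def random_chain(n_residues: int, seed: int = 0, chain_id: str = "A",
                 pdb_id: str = "0RND") -> ToySpec:
    """A random chain for oracle tests: uniform residue types, SS classes
    and SA values, coordinates in a box sized so that a nontrivial
    fraction of pairs falls inside the distance cutoff."""
    if not 2 <= n_residues <= 200:
        raise ValueError("n_residues must be in [2, 200]")
    rng = np.random.default_rng(seed)
    box = 6.0 * n_residues ** (1 / 3)
    residues = []
    for pos in range(1, n_residues + 1):
        aa = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
        anchor = rng.uniform(0, box, size=3)
        away = rng.normal(size=3)
        away /= np.linalg.norm(away)
        residues.append(ResidueSpec(
            aa_type=aa, chain_id=chain_id, author_number=pos,
            ss_class=SS_CLASSES[rng.integers(4)],
            rel_sa=float(rng.uniform(1e-6, 110.0)),
            functional_atoms=_functional_positions(aa, anchor, away),
            ca=tuple(anchor + rng.normal(scale=1.0, size=3)),
        ))
    return ToySpec(pdb_id=pdb_id, residues=residues)


def build_chain(spec: ToySpec) -> ChainModel:
    """Realize a ToySpec as an in-memory validated chain (the same model
    `write_fixture` + parsing + validation produces)."""
    chain = ChainModel(pdb_id=spec.pdb_id, chain_id=spec.residues[0].chain_id)
    for seq, rs in enumerate(spec.residues, start=1):
        atom_map = rs.atom_dict()
        atoms = [AtomRecord(n, np.array(c)) for n, c in atom_map.items()]
        func = np.array([atom_map[n] for n in FUNCTIONAL_ATOMS[rs.aa_type]])
        chain.residues.append(ResidueRecord(
            pdb_id=spec.pdb_id, chain_id=rs.chain_id, seq_index=seq,
            author_number=rs.author_number, aa_type=rs.aa_type,
            ss_class=rs.ss_class, sasa=rs.sasa, rel_sa=rs.rel_sa,
            atoms=atoms, functional_coords=func,
            ca_coords=np.array(atom_map["CA"]),
            midpoint=geometry.residue_midpoint(atoms),
        ))
    geometry.chain_center(chain)
    return chain


_ELEMENTS = {"C": "C", "N": "N", "O": "O", "S": "S"}


def _pdb_atom_line(serial: int, name: str, resname: str, chain: str,
                   resnum: int, xyz) -> str:
    name_field = name if len(name) == 4 else f" {name:<3s}"
    elem = _ELEMENTS.get(name[0], name[0])
    x, y, z = xyz
    return (f"ATOM  {serial:5d} {name_field} {resname:>3s} {chain}{resnum:4d}"
            f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {elem:>2s}")


def write_fixture(spec: ToySpec, out_dir,
                  annotation_format: str = "tabular") -> tuple[Path, Path]:
    """Write a ToySpec as a PDB coordinate file plus an annotation file.

    The annotation SASA column is back-computed from each residue's
    relative accessibility via the reference-area table, so parsing and
    validation reproduce the spec's shells exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = spec.pdb_id.lower()
    pdb_path = out_dir / f"{stem}.ent"
    lines = [f"HEADER    {'SYNTHETIC FIXTURE':<40s}{'01-JAN-00':>9s}"
             f"   {spec.pdb_id:<4s}"]
    serial = 0
    for rs in spec.residues:
        atom_map = rs.atom_dict()
        # CA first, then the remaining atoms in declaration order
        names = ["CA"] + [n for n in atom_map if n != "CA"]
        for name in names:
            serial += 1
            lines.append(_pdb_atom_line(serial, name, rs.aa_type, rs.chain_id,
                                        rs.author_number, atom_map[name]))
    lines.append("END")
    pdb_path.write_text("\n".join(lines) + "\n")

    if annotation_format == "tabular":
        ann_path = out_dir / f"{stem}.ann"
        rows = ["# synthetic annotation (tabular dialect)",
                "chain pdb_number aa ss acc"]
        for rs in spec.residues:
            rows.append(f"{rs.chain_id} {rs.author_number} {rs.aa_type} "
                        f"{_SS_TO_CODE[rs.ss_class]} {rs.sasa:.4f}")
        ann_path.write_text("\n".join(rows) + "\n")
    elif annotation_format == "hssp":
        ann_path = out_dir / f"{stem}.hssp"
        rows = [f"HSSP  SYNTHETIC MINI FILE FOR {spec.pdb_id}",
                "## RESIDUES AND SEQUENCE PROFILE",
                " SeqNo  PDBNo AA STRUCTURE BP1 BP2  ACC"]
        for seq, rs in enumerate(spec.residues, start=1):
            aa1 = THREE_TO_ONE[rs.aa_type]
            acc = int(round(rs.sasa))
            line = (f"{seq:5d}{rs.author_number:6d} {rs.chain_id} {aa1}  "
                    f"{_SS_TO_CODE[rs.ss_class]}")
            rows.append(f"{line:<34s}{acc:5d}")
        rows.append("##")
        ann_path.write_text("\n".join(rows) + "\n")
    else:
        raise ValueError(f"unknown annotation format {annotation_format!r}")
    return pdb_path, ann_path
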