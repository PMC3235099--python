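"""Read coordinate (PDB) and per-residue annotation (HSSP) files and merge
them into validated chains.

Coordinate files supply atom positions; annotation files supply residue
type, secondary structure, solvent accessibility, and the correspondence
between annotation rows and coordinate-file residue numbering (the two
numberings can differ).  `merge_and_validate` joins the two sources and
discards any residue that lacks a required field, keeping the rest of the
chain.

Besides genuine HSSP residue blocks, a simple whitespace-delimited
annotation dialect is accepted (columns: chain, pdb_number, aa, ss, acc;
'#' starts a comment), convenient for small synthetic inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

from . import geometry
from .constants import AMINO_ACIDS, FUNCTIONAL_ATOMS, ONE_TO_THREE, SS_CODE_MAP
from .model import AtomRecord, ChainModel, ResidueRecord

ANNOTATION_COLUMNS = ["chain_id", "pdb_number", "aa_type", "ss_class", "sasa",
                      "valid", "reason"]


class EmptyStructureError(ValueError):
    """Coordinate file contains no usable ATOM records."""


class AnnotationFormatError(ValueError):
    """Annotation file lacks required columns or structure."""


def parse_structure_file(path, allowed_chains: set[str] | None = None) -> list[ChainModel]:
    """Load ATOM records of a PDB file into per-chain models.

    HETATM records, waters and alternate conformers beyond the first are
    excluded.  Only the first model of multi-model files is read.  The
    returned chains carry coordinates only; annotation fields are filled by
    `merge_and_validate`.
    """
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.remove_alternative_conformations()
    st.remove_waters()
    pdb_id = (st.name or "XXXX")[:4].upper().ljust(4, "X")
    chains: list[ChainModel] = []
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]
    for ch in model:
        if allowed_chains is not None and ch.name not in allowed_chains:
            continue
        cm = ChainModel(pdb_id=pdb_id, chain_id=ch.name)
        seq = 0
        for res in ch:
            if res.het_flag != "A":  # HETATM (ligands, ions) excluded
                continue
            atoms = [AtomRecord(a.name, np.array([a.pos.x, a.pos.y, a.pos.z]))
                     for a in res]
            if not atoms:
                continue
            seq += 1
            cm.residues.append(ResidueRecord(
                pdb_id=pdb_id, chain_id=ch.name, seq_index=seq,
                author_number=res.seqid.num, aa_type=res.name.upper(),
                atoms=atoms,
            ))
        if cm.residues:
            chains.append(cm)
    if not chains:
        raise EmptyStructureError(f"{path}: no ATOM records in selected chains")
    return chains


def _finish_row(rows, chain_id, pdb_number, aa, ss_code, acc) -> None:
    valid, reason = True, ""
    aa3 = None
    if pdb_number is None or not chain_id:
        valid, reason = False, "missing coordinate-file correspondence"
    if valid:
        aa = (aa or "").strip().upper()
        aa3 = aa if len(aa) == 3 else ONE_TO_THREE.get(aa)
        if aa3 is None or aa3 not in AMINO_ACIDS:
            valid, reason = False, f"nonstandard residue type {aa!r}"
    ss_class = None
    if valid:
        code = (ss_code or "").strip().upper() or ""
        if code in SS_CODE_MAP or len(code) == 0:
            ss_class = SS_CODE_MAP.get(code, "coil")
        elif len(code) == 1:
            ss_class = "coil"  # unannotated single-letter state
        else:
            valid, reason = False, f"unparsable SS code {ss_code!r}"
    sasa = np.nan
    if valid:
        try:
            sasa = float(acc)
            if sasa < 0:
                raise ValueError
        except (TypeError, ValueError):
            valid, reason = False, f"unparsable SASA {acc!r}"
    rows.append({
        "chain_id": chain_id, "pdb_number": pdb_number, "aa_type": aa3,
        "ss_class": ss_class, "sasa": sasa, "valid": valid, "reason": reason,
    })


def _parse_hssp(lines: list[str]) -> pd.DataFrame:
    """Parse the residue block of an HSSP file.

    Assumed fixed columns (DSSP-style residue lines): coordinate-file
    residue number in cols 6-11, chain in 12-13, one-letter AA in 14-15,
    SS code around col 17, ACC in cols 35-39.
    """
    rows: list[dict] = []
    in_block = False
    for line in lines:
        stripped = line.lstrip()
        if not in_block and "RESIDUE" in line and (
                stripped.startswith("#") or stripped.startswith("SeqNo")):
            in_block = True
            continue
        if in_block and stripped.startswith("SeqNo"):
            continue
        if in_block and line.startswith("##"):
            break
        if not in_block or len(line) < 15:
            continue
        num_field = line[5:11].strip()
        try:
            # insertion-coded numbers like "  12A" keep the numeric part
            pdb_number = int("".join(c for c in num_field if c in "-0123456789"))
        except ValueError:
            pdb_number = None
        chain_id = line[11:13].strip()
        aa1 = line[13:15].strip()
        ss_code = line[16:18].strip()[:1] if len(line) > 16 else " "
        acc = line[34:39].strip() if len(line) >= 39 else ""
        if aa1 == "!":  # chain-break marker
            continue
        aa3 = ONE_TO_THREE.get(aa1.upper(), aa1)
        _finish_row(rows, chain_id, pdb_number, aa3, ss_code, acc)
    if not rows:
        raise AnnotationFormatError("no residue rows found in HSSP block")
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def _parse_tabular(lines: list[str]) -> pd.DataFrame:
    rows: list[dict] = []
    header: list[str] | None = None
    required = {"chain", "pdb_number", "aa", "ss", "acc"}
    for line in lines:
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        toks = body.split()
        if header is None:
            header = [t.lower() for t in toks]
            if not required.issubset(header):
                raise AnnotationFormatError(
                    f"annotation table must have columns {sorted(required)}, "
                    f"got {header}")
            continue
        rec = dict(zip(header, toks))
        try:
            pdb_number = int(rec.get("pdb_number", ""))
        except ValueError:
            pdb_number = None
        _finish_row(rows, rec.get("chain", ""), pdb_number, rec.get("aa"),
                    rec.get("ss", ""), rec.get("acc"))
    if header is None:
        raise AnnotationFormatError("empty annotation file")
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def parse_annotation_file(path) -> pd.DataFrame:
    """Read per-residue annotation (HSSP or the tabular dialect).

    Returns a table with columns chain_id, pdb_number, aa_type, ss_class,
    sasa, valid, reason.  Rows missing a field are flagged invalid rather
    than dropped, so the discard report can name them.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if lines and lines[0].startswith("HSSP"):
        return _parse_hssp(lines)
    return _parse_tabular(lines)


@dataclass
class DiscardReport:
    """Residues removed during validation, with the reason for each."""

    discarded: list[tuple[str, int, str]] = field(default_factory=list)
    # (chain_id, author_number, reason)

    def add(self, chain_id: str, author_number: int, reason: str) -> None:
        self.discarded.append((chain_id, author_number, reason))

    def __len__(self) -> int:
        return len(self.discarded)


def merge_and_validate(
    chains: list[ChainModel], annotations: pd.DataFrame
) -> tuple[list[ChainModel], DiscardReport]:
    """Join coordinates with annotation and keep only complete residues.

    A residue is retained iff it has: a matching valid annotation row
    (joined on chain id + coordinate-file residue number), a standard
    residue type, CA coordinates, and all functional atoms for its type.
    Retained residues get consecutive ``seq_index`` values, relative
    accessibility, midpoint, and whole-chain center geometry.  Chains left
    with no residues are dropped with a warning.
    """
    report = DiscardReport()
    ann_by_key: dict[tuple[str, int], pd.Series] = {}
    for _, row in annotations.iterrows():
        if row["pdb_number"] is not None and not pd.isna(row["pdb_number"]):
            ann_by_key[(str(row["chain_id"]), int(row["pdb_number"]))] = row

    out: list[ChainModel] = []
    for chain in chains:
        kept: list[ResidueRecord] = []
        for res in chain.residues:
            row = ann_by_key.get((res.chain_id, res.author_number))
            if row is None:
                report.add(res.chain_id, res.author_number, "no annotation match")
                continue
            if not row["valid"]:
                report.add(res.chain_id, res.author_number,
                           f"invalid annotation: {row['reason']}")
                continue
            aa = row["aa_type"]
            if aa not in AMINO_ACIDS:
                report.add(res.chain_id, res.author_number,
                           f"nonstandard residue type {aa!r}")
                continue
            ca = res.atom("CA")
            if ca is None:
                report.add(res.chain_id, res.author_number, "missing CA atom")
                continue
            func = [res.atom(name) for name in FUNCTIONAL_ATOMS[aa]]
            if any(a is None for a in func):
                report.add(res.chain_id, res.author_number,
                           "missing functional atom")
                continue
            res.aa_type = aa
            res.ss_class = row["ss_class"]
            res.sasa = float(row["sasa"])
            res.rel_sa = geometry.relative_accessibility(res.sasa, aa)
            res.ca_coords = ca.coords
            res.functional_coords = np.array([a.coords for a in func])
            res.midpoint = geometry.residue_midpoint(res.atoms)
            kept.append(res)
        if not kept:
            warnings.warn(
                f"chain {chain.pdb_id}/{chain.chain_id} has no valid residues; dropped",
                stacklevel=2)
            continue
        for i, res in enumerate(kept, start=1):
            res.seq_index = i
        new_chain = ChainModel(pdb_id=chain.pdb_id, chain_id=chain.chain_id,
                               residues=kept)
        geometry.chain_center(new_chain)
        out.append(new_chain)
    return out, report
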