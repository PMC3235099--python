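"""Back-map tensor cells to concrete residue pairs.

A query constraint selects cells; the index store returns, for each
selected cell, the identifier strings of every pair that was counted there,
decoded into (structure, residue 1, residue 2) hits.  Hits can be exported
as residue-selection commands for a standard molecular viewer.
"""

from __future__ import annotations

from dataclasses import dataclass

from .query import QuerySpec
from .tensorize import BinScheme, IndexStore, PairIndexError, decode_pair_index


class CorruptIndexError(ValueError):
    """A stored pair string failed to decode; names the offending row."""


@dataclass
class PairHit:
    """One concrete residue pair behind a tensor cell."""

    pdb_id: str
    residue1: tuple[int, str]  # (author_number, chain_id)
    residue2: tuple[int, str]
    cell: tuple


def select_cells(index: IndexStore, spec: QuerySpec,
                 scheme: BinScheme | None = None) -> list[tuple]:
    """All populated cells whose coordinates satisfy every constraint
    (display axes are ignored)."""
    scheme = scheme or BinScheme()
    from .tensorize import DIMENSIONS

    sel = [frozenset(spec.bins_for(dim, scheme)) for dim in DIMENSIONS]
    return [c for c in sorted(index.cells)
            if all(c[k] in sel[k] for k in range(8))]


def retrieve_pairs(index: IndexStore, cells: list[tuple]) -> list[PairHit]:
    """Decode every stored pair string of the given cells, in insertion
    order within each cell."""
    hits: list[PairHit] = []
    for cell in cells:
        for row, s in enumerate(index.cells.get(cell, [])):
            try:
                pdb_id, r1, r2 = decode_pair_index(s)
            except PairIndexError as exc:
                raise CorruptIndexError(
                    f"cell {cell}, row {row}: {exc}") from exc
            hits.append(PairHit(pdb_id=pdb_id, residue1=r1, residue2=r2,
                                cell=cell))
    return hits


def write_hits_tsv(hits: list[PairHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("pdb_id\tres1\tchain1\tres2\tchain2\tcell\n")
        for h in hits:
            fh.write(f"{h.pdb_id}\t{h.residue1[0]}\t{h.residue1[1]}"
                     f"\t{h.residue2[0]}\t{h.residue2[1]}"
                     f"\t{','.join(map(str, h.cell))}\n")


def write_selections(hits: list[PairHit], path) -> None:
    """Emit one viewer selection command per hit (PyMOL-style syntax), so
    the pairs can be inspected in any structure viewer."""
    with open(path, "w") as fh:
        for i, h in enumerate(hits, start=1):
            fh.write(
                f"# {h.pdb_id}: {h.residue1[0]}{h.residue1[1]}"
                f" - {h.residue2[0]}{h.residue2[1]}\n"
                f"select pair{i:04d}, (chain {h.residue1[1]} and resi "
                f"{h.residue1[0]}) or (chain {h.residue2[1]} and resi "
                f"{h.residue2[0]})\n")
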