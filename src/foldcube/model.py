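"""In-memory model: atoms, validated residues, chains.

A `ChainModel` is the analysis unit: one polypeptide chain whose residues
have passed validation (coordinates merged with per-residue annotation).
Residues are indexed 1..n consecutively after validation, so sequence
distance is a difference of `seq_index` values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DegenerateInputError(ValueError):
    """An operation received an empty or degenerate input."""


@dataclass
class AtomRecord:
    """One atom: PDB atom name and Cartesian coordinates in Å."""

    name: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")


@dataclass
class ResidueRecord:
    """One validated residue with geometry and annotation.

    Attributes
    ----------
    seq_index : 1-based position within the chain after validation
        (consecutive; used for sequence distance).
    author_number : residue number as written in the coordinate file
        (used in pair index strings).
    rel_sa : relative solvent accessibility in percent; may exceed 100
        when the observed SASA exceeds the Gly-X-Gly reference area.
    functional_coords : coordinates of the residue's 1-2 functional atoms.
    midpoint : arithmetic mean of all atom coordinates, Å.
    """

    pdb_id: str
    chain_id: str
    seq_index: int
    author_number: int
    aa_type: str
    ss_class: str | None = None
    sasa: float | None = None
    rel_sa: float | None = None
    atoms: list[AtomRecord] = field(default_factory=list)
    functional_coords: np.ndarray | None = None
    ca_coords: np.ndarray | None = None
    midpoint: np.ndarray | None = None

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class ChainModel:
    """Ordered residues of one chain plus derived whole-chain geometry."""

    pdb_id: str
    chain_id: str
    residues: list[ResidueRecord] = field(default_factory=list)
    center: np.ndarray | None = None
    center_distances: np.ndarray | None = None

    @property
    def chain_length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)
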