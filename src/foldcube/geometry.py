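"""Residue and chain geometry: midpoints, protein center, solvent shells.

The protein is modelled as a set of concentric solvent-accessibility
shells: residues are grouped by relative solvent accessibility (10 %-wide
bins, with fully buried SA=0 and over-exposed SA>100 treated explicitly),
and each shell's mean distance to the chain's geometric center gives the
shell a nominal "thickness" anchor.  This is an approximation that treats
the chain as globular.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import REFERENCE_AREAS, SS_CLASSES
from .model import ChainModel, DegenerateInputError


def residue_midpoint(atoms) -> np.ndarray:
    """Geometric midpoint of a residue: mean of its atom coordinates (Å)."""
    if not atoms:
        raise DegenerateInputError("residue has no atoms")
    return np.mean([a.coords for a in atoms], axis=0)


def chain_center(chain: ChainModel) -> np.ndarray:
    """Geometric center of a chain: mean of residue midpoints.

    Also fills ``chain.center`` and ``chain.center_distances`` (Euclidean
    distance from each residue midpoint to the center).  The center is
    computed per chain, the analysis unit.
    """
    if not chain.residues:
        raise DegenerateInputError(f"chain {chain.chain_id!r} has no residues")
    mids = np.array([r.midpoint for r in chain.residues], dtype=float)
    if np.any([r.midpoint is None for r in chain.residues]):
        raise DegenerateInputError("all residues need a midpoint")
    center = mids.mean(axis=0)
    chain.center = center
    chain.center_distances = np.linalg.norm(mids - center, axis=1)
    return center


def relative_accessibility(sasa: float, aa_type: str) -> float:
    """Convert absolute SASA (Å²) to percent of the residue's maximal
    Gly-X-Gly tripeptide area.  Linear in SASA; may exceed 100 %."""
    if sasa < 0:
        raise ValueError(f"negative SASA {sasa}")
    try:
        ref = REFERENCE_AREAS[aa_type]
    except KeyError:
        raise KeyError(f"no reference area for residue type {aa_type!r}") from None
    return 100.0 * sasa / ref


@dataclass
class ShellProfile:
    """Per-SA-bin residue counts and mean distance to the chain center.

    ``mean_distance`` is NaN for empty shells (undefined, never zero).
    """

    table: pd.DataFrame  # columns: sa_bin, count, mean_distance

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def shell_thickness_profile(chains: list[ChainModel], scheme) -> ShellProfile:
    """Mean center distance of the residues in each solvent shell."""
    n_bins = len(scheme.sa_labels)
    counts = np.zeros(n_bins, dtype=int)
    sums = np.zeros(n_bins, dtype=float)
    for chain in chains:
        if chain.center_distances is None:
            chain_center(chain)
        for res, dist in zip(chain.residues, chain.center_distances):
            b = scheme.sa_bin(res.rel_sa)
            counts[b] += 1
            sums[b] += dist
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    table = pd.DataFrame(
        {"sa_bin": list(scheme.sa_labels), "count": counts, "mean_distance": means}
    )
    return ShellProfile(table)


def sa_ss_distribution(chains: list[ChainModel], aa_type: str, scheme) -> pd.DataFrame:
    """Count residues of one type per (SA shell, secondary-structure class).

    Returns a 12x4 table (rows: SA bins, columns: helix/strand/turn/coil);
    its row sums are the residue type's solvent-shell histogram.
    """
    counts = np.zeros((len(scheme.sa_labels), len(SS_CLASSES)), dtype=int)
    for chain in chains:
        for res in chain.residues:
            if res.aa_type != aa_type:
                continue
            counts[scheme.sa_bin(res.rel_sa), SS_CLASSES.index(res.ss_class)] += 1
    return pd.DataFrame(counts, index=list(scheme.sa_labels), columns=list(SS_CLASSES))
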