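"""Build the 8D fold tensor: bin scheme, pair detection, accumulation,
index strings, and the shuffled-reference null model.

Every residue pair that (a) lies in one chain, (b) shares a solvent-
accessibility shell and (c) has a functional-atom distance below 8.25 Å is
one observation.  Observations are counted in a sparse 8-dimensional tensor
over (AA1, AA2, SA, D, SS1, SS2, CL, SD):

    AA1, AA2 — residue types (20 bins each)
    SA       — shared solvent-accessibility shell (12 bins)
    D        — functional-atom distance (14 half-open 0.5 Å bins to 8.25 Å)
    SS1, SS2 — secondary-structure classes (4 bins each)
    CL       — chain length (12 bins)
    SD       — sequence distance (6 bins: 0..4, >4)

for a total of 20*20*12*14*4*4*12*6 = 77,414,400 cells.  Alongside the
counts, an index store records a 14-character identifier string per pair
("1ABC0102A1030B") so any cell can be mapped back to concrete residue pairs.

The reference tensor is the same construction applied to chains whose
residue-type labels have been randomly permuted within the chain (all other
per-position attributes kept), averaged over a number of shuffles; the
observed/reference ratio measures over-representation against random
packing of the same composition.
"""

from __future__ import annotations

import hashlib
import re
import zlib
from bisect import bisect_left
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import (
    AA_INDEX,
    AA_LABELS,
    AMINO_ACIDS,
    DISTANCE_CUTOFF,
    SS_CLASSES,
    SS_INDEX,
)
from .model import ChainModel, ResidueRecord

DIMENSIONS: tuple[str, ...] = ("AA1", "AA2", "SA", "D", "SS1", "SS2", "CL", "SD")


def _interval_labels(prefix: str, edges: list[float], fmt=lambda v: f"{v:g}") -> list[str]:
    labels = [f"{prefix}<={fmt(edges[0])}"]
    for lo, hi in zip(edges, edges[1:]):
        labels.append(f"{fmt(lo)}<{prefix}<={fmt(hi)}")
    labels.append(f"{prefix}>{fmt(edges[-1])}")
    return labels


@dataclass(frozen=True)
class BinScheme:
    """The eight dimensions' labelled half-open bins.

    Numeric dimensions use right-closed intervals (lo < x <= hi); the first
    bin is (-inf, edge0] and, where an open top bin exists (SA, CL), the
    last is (edge_last, inf).  The distance dimension has no open top bin:
    pairs beyond its last edge are not observations at all.
    """

    sa_edges: tuple[float, ...] = tuple(float(v) for v in range(0, 101, 10))
    d_edges: tuple[float, ...] = tuple(round(1.75 + 0.5 * i, 2) for i in range(14))
    cl_edges: tuple[float, ...] = tuple(float(v) for v in range(0, 1001, 100))
    sd_max_exact: int = 4

    @property
    def aa_labels(self) -> tuple[str, ...]:
        return AA_LABELS

    @property
    def ss_labels(self) -> tuple[str, ...]:
        return SS_CLASSES

    @property
    def sa_labels(self) -> tuple[str, ...]:
        return tuple(_interval_labels("SA", list(self.sa_edges)))

    @property
    def d_labels(self) -> tuple[str, ...]:
        # no open top bin: the last distance edge is the pair cutoff
        return tuple(_interval_labels("D", list(self.d_edges))[:-1])

    @property
    def cl_labels(self) -> tuple[str, ...]:
        return tuple(_interval_labels("CL", list(self.cl_edges)))

    @property
    def sd_labels(self) -> tuple[str, ...]:
        return tuple(str(i) for i in range(self.sd_max_exact + 1)) + (
            f">{self.sd_max_exact}",
        )

    @property
    def shape(self) -> tuple[int, ...]:
        return (
            len(self.aa_labels), len(self.aa_labels), len(self.sa_labels),
            len(self.d_labels), len(self.ss_labels), len(self.ss_labels),
            len(self.cl_labels), len(self.sd_labels),
        )

    @property
    def total_cells(self) -> int:
        return int(np.prod(self.shape))

    def labels(self, dim: str) -> tuple[str, ...]:
        return {
            "AA1": self.aa_labels, "AA2": self.aa_labels, "SA": self.sa_labels,
            "D": self.d_labels, "SS1": self.ss_labels, "SS2": self.ss_labels,
            "CL": self.cl_labels, "SD": self.sd_labels,
        }[dim]

    # --- bin assignment (half-open, right-closed) ---

    def aa_bin(self, aa_type: str) -> int:
        return AA_INDEX[aa_type.upper()]

    def ss_bin(self, ss_class: str) -> int:
        return SS_INDEX[ss_class]

    def sa_bin(self, rel_sa: float) -> int:
        return bisect_left(self.sa_edges, rel_sa)

    def d_bin(self, distance: float) -> int:
        if distance > self.d_edges[-1]:
            raise ValueError(f"distance {distance} beyond the pair cutoff")
        return bisect_left(self.d_edges, distance)

    def cl_bin(self, chain_length: int) -> int:
        return bisect_left(self.cl_edges, chain_length)

    def sd_bin(self, seq_distance: int) -> int:
        if seq_distance < 0:
            raise ValueError("sequence distance must be non-negative")
        return min(seq_distance, self.sd_max_exact + 1)

    @property
    def fingerprint(self) -> str:
        spec = repr((AMINO_ACIDS, self.sa_edges, self.d_edges, SS_CLASSES,
                     self.cl_edges, self.sd_max_exact))
        return hashlib.sha1(spec.encode()).hexdigest()[:12]


def default_bin_scheme() -> BinScheme:
    """The standard bin scheme (edges as listed in the module docstring)."""
    return BinScheme()


@dataclass
class PairObservation:
    """One observed residue pair, with its 8D cell coordinates."""

    coords: tuple[int, int, int, int, int, int, int, int]
    raw_distance: float
    residue_refs: tuple[tuple[int, str], tuple[int, str]]  # (author_number, chain)
    pdb_id: str


@dataclass
class FoldTensor:
    """Sparse 8D count tensor: map from cell coordinates to counts.

    ``kind`` is "observed" (integer counts) or "reference" (average over
    shuffles).  Reference counts are stored as an integer sum plus the
    shuffle count ``divisor`` so averaging stays exact; cell values are
    sum/divisor.
    """

    shape: tuple[int, ...]
    kind: str = "observed"
    divisor: int = 1
    scheme_fingerprint: str = ""
    counts: dict[tuple, float] = field(default_factory=dict)

    def add(self, coords: tuple, amount: float = 1) -> None:
        if any(c < 0 or c >= n for c, n in zip(coords, self.shape)):
            raise IndexError(f"cell {coords} outside tensor shape {self.shape}")
        self.counts[coords] = self.counts.get(coords, 0) + amount

    def value(self, coords: tuple) -> float:
        return self.counts.get(coords, 0) / self.divisor

    def items(self):
        """Iterate (coords, value) over non-empty cells."""
        for c, v in self.counts.items():
            yield c, v / self.divisor

    def total(self) -> float:
        return sum(self.counts.values()) / self.divisor

    @property
    def n_filled(self) -> int:
        return len(self.counts)


@dataclass
class IndexStore:
    """Sparse map from cell coordinates to pair identifier strings."""

    cells: dict[tuple, list[str]] = field(default_factory=dict)

    def add(self, coords: tuple, pair_string: str) -> None:
        self.cells.setdefault(coords, []).append(pair_string)

    def total(self) -> int:
        return sum(len(v) for v in self.cells.values())


def functional_atom_distance(r1: ResidueRecord, r2: ResidueRecord) -> float:
    """Minimum Euclidean distance over the two residues' functional atoms.

    Multi-atom functional groups (Arg NH1/NH2, Asp OD1/OD2, ...) reduce by
    the minimum, the closest-atom convention used for salt bridges.
    """
    if r1.functional_coords is None or r2.functional_coords is None:
        raise ValueError("both residues need functional-atom coordinates")
    a = np.atleast_2d(r1.functional_coords)
    b = np.atleast_2d(r2.functional_coords)
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(d.min())


def enumerate_pairs(chain: ChainModel, scheme: BinScheme) -> list[PairObservation]:
    """All residue pairs of a chain that share an SA shell and lie within
    the distance cutoff.

    Each unordered pair is returned once, in canonical order: the residue
    with the lower ``seq_index`` contributes AA1 and SS1.
    """
    obs: list[PairObservation] = []
    residues = sorted(chain.residues, key=lambda r: r.seq_index)
    cl = scheme.cl_bin(chain.chain_length)
    sa_bins = [scheme.sa_bin(r.rel_sa) for r in residues]
    n = len(residues)
    for i in range(n):
        ri = residues[i]
        for j in range(i + 1, n):
            rj = residues[j]
            if sa_bins[i] != sa_bins[j]:
                continue
            d = functional_atom_distance(ri, rj)
            if d >= DISTANCE_CUTOFF:
                continue
            coords = (
                scheme.aa_bin(ri.aa_type), scheme.aa_bin(rj.aa_type),
                sa_bins[i], scheme.d_bin(d),
                scheme.ss_bin(ri.ss_class), scheme.ss_bin(rj.ss_class),
                cl, scheme.sd_bin(abs(rj.seq_index - ri.seq_index)),
            )
            obs.append(PairObservation(
                coords=coords,
                raw_distance=d,
                residue_refs=((ri.author_number, ri.chain_id),
                              (rj.author_number, rj.chain_id)),
                pdb_id=chain.pdb_id,
            ))
    return obs


def accumulate(
    observations: list[PairObservation],
    tensor: FoldTensor,
    index: IndexStore | None = None,
) -> None:
    """Add one count per observation to the tensor, and one index string
    per observation to the index store (if given)."""
    for ob in observations:
        tensor.add(ob.coords, 1)
        if index is not None:
            index.add(ob.coords, encode_pair_index(ob.pdb_id, *ob.residue_refs))


class PairIndexError(ValueError):
    """A pair identifier string could not be encoded or decoded."""


_INDEX_RE = re.compile(r"^(.{4})(\d{4})(\S)(\d{4})(\S)$")


def encode_pair_index(pdb_id: str, r1: tuple[int, str], r2: tuple[int, str]) -> str:
    """Fixed-width pair identifier, e.g. ("1ABC",(102,"A"),(1030,"B")) ->
    "1ABC0102A1030B"."""
    if len(pdb_id) != 4:
        raise PairIndexError(f"pdb id must be 4 characters, got {pdb_id!r}")
    parts = [pdb_id]
    for num, chain in (r1, r2):
        if not 0 <= num <= 9999:
            raise PairIndexError(f"residue number {num} does not fit 4 digits")
        if len(str(chain)) != 1:
            raise PairIndexError(f"chain id must be 1 character, got {chain!r}")
        parts.append(f"{num:04d}{chain}")
    return "".join(parts)


def decode_pair_index(s: str) -> tuple[str, tuple[int, str], tuple[int, str]]:
    m = _INDEX_RE.match(s)
    if not m or len(s) != 14:
        raise PairIndexError(f"malformed pair index string {s!r}")
    pdb_id, n1, c1, n2, c2 = m.groups()
    return pdb_id, (int(n1), c1), (int(n2), c2)


def shuffle_chain(chain: ChainModel, rng: np.random.Generator) -> ChainModel:
    """Randomly permute residue-type labels within the chain.

    Each position keeps its geometry (functional and CA coordinates,
    midpoint), SA values and secondary structure; only the type labels move,
    so the chain's amino-acid composition is preserved exactly and pair
    existence (which depends on position geometry and SA shells only) is
    unchanged.
    """
    perm = rng.permutation(len(chain.residues))
    new_residues = [
        replace(res, aa_type=chain.residues[k].aa_type)
        for res, k in zip(chain.residues, perm)
    ]
    return ChainModel(
        pdb_id=chain.pdb_id,
        chain_id=chain.chain_id,
        residues=new_residues,
        center=chain.center,
        center_distances=chain.center_distances,
    )


def _chain_seed_seq(seed: int | None, chain: ChainModel) -> np.random.SeedSequence:
    # stable per-chain stream, independent of processing order
    key = zlib.crc32(f"{chain.pdb_id}/{chain.chain_id}".encode())
    return np.random.SeedSequence(entropy=0 if seed is None else seed,
                                  spawn_key=(key,))


def build_observed(
    chains: list[ChainModel],
    scheme: BinScheme,
    with_index: bool = True,
) -> tuple[FoldTensor, IndexStore | None]:
    """Enumerate and accumulate all chains' pairs into a fresh tensor."""
    tensor = FoldTensor(shape=scheme.shape, kind="observed",
                        scheme_fingerprint=scheme.fingerprint)
    index = IndexStore() if with_index else None
    for chain in chains:
        accumulate(enumerate_pairs(chain, scheme), tensor, index)
    return tensor, index


def build_reference_tensor(
    chains: list[ChainModel],
    scheme: BinScheme,
    n_shuffles: int = 10,
    seed: int | None = None,
) -> FoldTensor:
    """Average tensor over ``n_shuffles`` label-shuffled copies of each chain.

    Counts are stored as the integer sum over shuffles with
    ``divisor = n_shuffles``, so the average is exact.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    tensor = FoldTensor(shape=scheme.shape, kind="reference",
                        divisor=n_shuffles, scheme_fingerprint=scheme.fingerprint)
    for chain in chains:
        streams = _chain_seed_seq(seed, chain).spawn(n_shuffles)
        for ss in streams:
            shuffled = shuffle_chain(chain, np.random.default_rng(ss))
            accumulate(enumerate_pairs(shuffled, scheme), tensor, None)
    return tensor


# --- persistence (plain-text sparse formats) ---


def save_tensor(tensor: FoldTensor, path) -> None:
    """Sparse coordinate-list TSV: one row per non-empty cell."""
    with open(path, "w") as fh:
        fh.write(f"# kind={tensor.kind}\n")
        fh.write(f"# scheme={tensor.scheme_fingerprint}\n")
        fh.write(f"# shape={','.join(map(str, tensor.shape))}\n")
        fh.write(f"# divisor={tensor.divisor}\n")
        fh.write("\t".join(f"c{i+1}" for i in range(8)) + "\tcount\n")
        for coords in sorted(tensor.counts):
            raw = tensor.counts[coords]
            fh.write("\t".join(map(str, coords)) + f"\t{raw:g}\n")


def load_tensor(path) -> FoldTensor:
    meta: dict[str, str] = {}
    counts: dict[tuple, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                k, _, v = line[1:].strip().partition("=")
                meta[k.strip()] = v.strip()
            elif line and not line.startswith("c1\t"):
                *cs, cnt = line.split("\t")
                val = float(cnt)
                counts[tuple(int(c) for c in cs)] = int(val) if val == int(val) else val
    shape = tuple(int(s) for s in meta["shape"].split(","))
    return FoldTensor(shape=shape, kind=meta.get("kind", "observed"),
                      divisor=int(meta.get("divisor", 1)),
                      scheme_fingerprint=meta.get("scheme", ""), counts=counts)


def save_index(index: IndexStore, path) -> None:
    with open(path, "w") as fh:
        for coords in sorted(index.cells):
            for s in index.cells[coords]:
                fh.write("\t".join(map(str, coords)) + f"\t{s}\n")


def load_index(path) -> IndexStore:
    store = IndexStore()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                continue
            store.add(tuple(int(c) for c in parts[:8]), parts[8])
    return store
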