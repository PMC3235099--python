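"""Shared fixtures and the independent brute-force pair oracle.

The oracle re-derives every bin assignment with its own arithmetic
(ceil-based interval indexing, explicit double loops over atoms and
residues) so it shares no code with the package's enumeration path.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

import foldcube as fc

settings.register_profile("repeatable", deadline=None, derandomize=True)
settings.load_profile("repeatable")

_ORACLE_AA_ORDER = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]
_ORACLE_SS_ORDER = ["helix", "strand", "turn", "coil"]


def _oracle_sa_bin(x: float) -> int:
    if x <= 0:
        return 0
    if x > 100:
        return 11
    return math.ceil(x / 10.0)


def _oracle_d_bin(d: float) -> int:
    if d <= 1.75:
        return 0
    return math.ceil((d - 1.75) / 0.5)


def _oracle_cl_bin(n: int) -> int:
    if n <= 0:
        return 0
    if n > 1000:
        return 11
    return math.ceil(n / 100.0)


def _oracle_sd_bin(sd: int) -> int:
    return sd if sd <= 4 else 5


def naive_pairs(chain: fc.ChainModel) -> set[tuple]:
    """O(n^2) reference enumeration: every unordered residue pair sharing a
    solvent shell with minimum functional-atom distance < 8.25 Å.

    Returns hashable tuples (coords, residue refs) for set comparison.
    """
    out = set()
    res = sorted(chain.residues, key=lambda r: r.seq_index)
    cl = _oracle_cl_bin(len(res))
    for i in range(len(res)):
        for j in range(len(res)):
            if j <= i:
                continue
            a, b = res[i], res[j]
            if _oracle_sa_bin(a.rel_sa) != _oracle_sa_bin(b.rel_sa):
                continue
            best = math.inf
            for pa in np.atleast_2d(a.functional_coords):
                for pb in np.atleast_2d(b.functional_coords):
                    best = min(best, math.dist(tuple(pa), tuple(pb)))
            if best >= 8.25:
                continue
            coords = (
                _ORACLE_AA_ORDER.index(a.aa_type),
                _ORACLE_AA_ORDER.index(b.aa_type),
                _oracle_sa_bin(a.rel_sa),
                _oracle_d_bin(best),
                _ORACLE_SS_ORDER.index(a.ss_class),
                _ORACLE_SS_ORDER.index(b.ss_class),
                cl,
                _oracle_sd_bin(abs(a.seq_index - b.seq_index)),
            )
            out.add((coords, (a.author_number, a.chain_id),
                     (b.author_number, b.chain_id)))
    return out


def observations_as_set(observations) -> set[tuple]:
    return {(ob.coords, *ob.residue_refs) for ob in observations}


@pytest.fixture(scope="session")
def scheme() -> fc.BinScheme:
    return fc.default_bin_scheme()


@pytest.fixture(scope="session")
def random_chains() -> list[fc.ChainModel]:
    """Twenty modest random chains reused across conservation tests."""
    return [fc.build_chain(fc.random_chain(25 + (s % 20), seed=s))
            for s in range(20)]


@pytest.fixture()
def disulphide_chain() -> fc.ChainModel:
    return fc.build_chain(fc.make_motif_chain("disulphide", seed=11))
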