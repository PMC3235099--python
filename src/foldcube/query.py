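"""Query the fold tensor: constrain dimensions, project onto 1-3 axes.

Modes
-----
absolute   counts from the observed tensor
reference  averaged counts from the shuffled-reference tensor
ratio      projected observed divided by projected reference; a value above
           1 marks over-representation relative to random packing.  Cells
           with observed > 0 but reference = 0 are masked as undefined
           rather than assigned an arbitrary large value.
warp       absolute heights paired with unit-normalized ratio colors.

The ratio is computed on the *projected* sums (project first, divide
second), so a 2D ratio map is the ratio of the two 2D aggregates.

Queries can be written in a small text language, e.g.::

    AA1=CYS AA2=CYS SS1=coil SS2=coil SD=>4 axes=D,SD mode=ratio

Constraints accept a single bin label (``AA1=LYS``, ``SS1=helix``,
``SD=>4``), a set (``AA1={ARG,LYS}``), or for the numeric dimensions a
range ``SA=20-40`` selecting every bin wholly inside the interval
(20, 40].  Unconstrained dimensions default to all bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import AA_INDEX, SS_INDEX
from .tensorize import DIMENSIONS, BinScheme, FoldTensor

_SWAP = {0: 1, 1: 0, 4: 5, 5: 4}  # AA1<->AA2, SS1<->SS2


class QueryError(ValueError):
    """Malformed query: unknown dimension, label, or incompatible inputs."""


@dataclass
class QuerySpec:
    """Constraint subsets per dimension plus display axes and mode."""

    constraints: dict[str, tuple[int, ...]] = field(default_factory=dict)
    axes: tuple[str, ...] = ()
    mode: str = "absolute"
    symmetrize: bool = False

    def __post_init__(self) -> None:
        if len(set(self.axes)) != len(self.axes):
            raise QueryError("axes must be distinct")
        if not 0 <= len(self.axes) <= 3:
            raise QueryError("1-3 axes supported")
        for dim in list(self.constraints) + list(self.axes):
            if dim not in DIMENSIONS:
                raise QueryError(f"unknown dimension {dim!r}")
        for dim, bins in self.constraints.items():
            if len(bins) == 0:
                raise QueryError(f"empty constraint subset for {dim}")

    def bins_for(self, dim: str, scheme: BinScheme) -> tuple[int, ...]:
        return self.constraints.get(dim, tuple(range(len(scheme.labels(dim)))))


@dataclass
class ProjectionResult:
    """Array over the selected axis bins, with labels and undefined-mask."""

    axes: tuple[str, ...]
    bin_labels: tuple[tuple[str, ...], ...]
    values: np.ndarray
    mask: np.ndarray  # True where undefined (ratio with reference 0)
    mode: str
    total: float

    def to_tsv(self, path) -> None:
        """Export as TSV: 2D as a labelled matrix, else long format.
        Masked (undefined) cells are written as NA."""
        with open(path, "w") as fh:
            if len(self.axes) == 2:
                fh.write(self.axes[0] + "\\" + self.axes[1] + "\t"
                         + "\t".join(self.bin_labels[1]) + "\n")
                for i, row_label in enumerate(self.bin_labels[0]):
                    cells = ["NA" if self.mask[i, j] else f"{self.values[i, j]:g}"
                             for j in range(self.values.shape[1])]
                    fh.write(row_label + "\t" + "\t".join(cells) + "\n")
            else:
                fh.write("\t".join(self.axes) + "\tvalue\n")
                for idx in np.ndindex(self.values.shape):
                    labels = [self.bin_labels[k][i] for k, i in enumerate(idx)]
                    v = "NA" if self.mask[idx] else f"{self.values[idx]:g}"
                    fh.write("\t".join(labels) + "\t" + v + "\n")


def _oriented_cells(coords: tuple, value: float, symmetrize: bool):
    """Yield the cell and, under symmetrization, its AA/SS-swapped image
    (once only when the swap is a fixed point)."""
    yield coords, value
    if symmetrize:
        swapped = tuple(coords[_SWAP.get(k, k)] for k in range(len(coords)))
        if swapped != coords:
            yield swapped, value


def project(tensor: FoldTensor, spec: QuerySpec, scheme: BinScheme | None = None
            ) -> ProjectionResult:
    """Sum counts over all non-axis dimensions, restricted to the
    constraint subsets."""
    scheme = scheme or BinScheme()
    if tensor.shape != scheme.shape:
        raise QueryError("tensor shape does not match bin scheme")
    axes = spec.axes
    axis_dims = [DIMENSIONS.index(a) for a in axes]
    sel = []
    for dim in DIMENSIONS:
        bins = spec.bins_for(dim, scheme)
        labels = scheme.labels(dim)
        for b in bins:
            if not 0 <= b < len(labels):
                raise QueryError(f"bin index {b} out of range for {dim}")
        sel.append(frozenset(bins))
    pos_maps = [{b: i for i, b in enumerate(sorted(sel[k]))} for k in axis_dims]
    values = np.zeros(tuple(len(m) for m in pos_maps))  # 0-d if no axes
    for coords, value in tensor.items():
        for c, v in _oriented_cells(coords, value, spec.symmetrize):
            if all(c[k] in sel[k] for k in range(8)):
                values[tuple(pos_maps[a][c[k]]
                             for a, k in enumerate(axis_dims))] += v
    bin_labels = tuple(
        tuple(scheme.labels(a)[b] for b in sorted(sel[DIMENSIONS.index(a)]))
        for a in axes
    )
    if not axes:  # grand total of the selection
        axes, bin_labels, values = ("total",), (("total",),), values.reshape(1)
    return ProjectionResult(
        axes=axes, bin_labels=bin_labels, values=values,
        mask=np.zeros_like(values, dtype=bool), mode=spec.mode or "absolute",
        total=float(values.sum()),
    )


def ratio_project(observed: FoldTensor, reference: FoldTensor, spec: QuerySpec,
                  scheme: BinScheme | None = None) -> ProjectionResult:
    """Projected observed counts divided by projected reference counts.

    obs = ref = 0 gives 0; obs > 0 with ref = 0 is masked undefined.
    """
    if observed.shape != reference.shape:
        raise QueryError("observed and reference tensors have different shapes")
    if (observed.scheme_fingerprint and reference.scheme_fingerprint
            and observed.scheme_fingerprint != reference.scheme_fingerprint):
        raise QueryError("observed and reference tensors use different bin schemes")
    obs = project(observed, replace(spec, mode="absolute"), scheme)
    ref = project(reference, replace(spec, mode="reference"), scheme)
    values = np.zeros_like(obs.values)
    mask = np.zeros_like(obs.values, dtype=bool)
    nonzero_ref = ref.values > 0
    values[nonzero_ref] = obs.values[nonzero_ref] / ref.values[nonzero_ref]
    mask[(~nonzero_ref) & (obs.values > 0)] = True
    return ProjectionResult(axes=obs.axes, bin_labels=obs.bin_labels,
                            values=values, mask=mask, mode="ratio",
                            total=obs.total)


def normalize_unit(result: ProjectionResult) -> ProjectionResult:
    """Scale defined values into [0, 1] by the maximum defined value.
    Idempotent; all-zero or all-masked input is returned unchanged."""
    if result.mode != "ratio":
        raise QueryError("normalize_unit applies to ratio-mode results")
    defined = result.values[~result.mask]
    if defined.size == 0 or defined.max() <= 0:
        return result
    values = result.values.copy()
    values[~result.mask] = defined / defined.max()
    return replace(result, values=values)


@dataclass
class WarpResult:
    """Topographic composite: heights are absolute counts, colors the
    unit-normalized ratio (red = most over-represented)."""

    axes: tuple[str, ...]
    bin_labels: tuple[tuple[str, ...], ...]
    heights: np.ndarray
    colors: np.ndarray
    mask: np.ndarray


def warp_compose(observed_result: ProjectionResult,
                 ratio_result: ProjectionResult) -> WarpResult:
    if (observed_result.axes != ratio_result.axes
            or observed_result.bin_labels != ratio_result.bin_labels):
        raise QueryError("warp inputs must share axes and constraint subsets")
    norm = normalize_unit(ratio_result)
    return WarpResult(axes=observed_result.axes,
                      bin_labels=observed_result.bin_labels,
                      heights=observed_result.values, colors=norm.values,
                      mask=norm.mask)


# --- query mini-language ---

_NUMERIC_DIMS = {"SA", "D", "CL"}


def _label_to_bin(dim: str, token: str, scheme: BinScheme) -> int:
    token = token.strip()
    if dim in ("AA1", "AA2"):
        aa = token.upper()
        if aa in AA_INDEX:
            return AA_INDEX[aa]
        raise QueryError(f"unknown amino acid {token!r}")
    if dim in ("SS1", "SS2"):
        ss = token.lower()
        if ss in SS_INDEX:
            return SS_INDEX[ss]
        raise QueryError(f"unknown secondary-structure class {token!r}")
    if dim == "SD":
        labels = scheme.sd_labels
        if token in labels:
            return labels.index(token)
        raise QueryError(f"unknown sequence-distance bin {token!r}")
    labels = scheme.labels(dim)
    if token in labels:
        return labels.index(token)
    raise QueryError(f"unknown {dim} bin label {token!r}")


def _range_to_bins(dim: str, lo: float, hi: float, scheme: BinScheme
                   ) -> tuple[int, ...]:
    edges = {"SA": scheme.sa_edges, "D": scheme.d_edges,
             "CL": scheme.cl_edges}[dim]
    n_bins = len(scheme.labels(dim))
    bins = []
    for b in range(n_bins):
        b_lo = -np.inf if b == 0 else edges[b - 1]
        b_hi = np.inf if b >= len(edges) else edges[b]
        if b_lo >= lo and b_hi <= hi:
            bins.append(b)
    if not bins:
        raise QueryError(f"range {lo}-{hi} covers no whole {dim} bin")
    return tuple(bins)


def parse_query(text: str) -> QuerySpec:
    """Parse the documented query mini-language into a QuerySpec."""
    scheme = BinScheme()
    constraints: dict[str, tuple[int, ...]] = {}
    axes: tuple[str, ...] = ()
    mode = "absolute"
    symmetrize = False
    pos = 0
    for token in text.split():
        pos = text.index(token, pos)
        if "=" not in token:
            raise QueryError(f"expected KEY=VALUE at position {pos}: {token!r}")
        key, _, value = token.partition("=")
        key_u = key.strip().upper()
        if key.lower() == "axes":
            axes = tuple(a.strip().upper() for a in value.split(","))
            for a in axes:
                if a not in DIMENSIONS:
                    raise QueryError(f"unknown axis {a!r} at position {pos}")
        elif key.lower() == "mode":
            if value not in ("absolute", "reference", "ratio", "warp"):
                raise QueryError(f"unknown mode {value!r} at position {pos}")
            mode = value
        elif key.lower() == "symmetrize":
            symmetrize = value.lower() in ("1", "on", "true", "yes")
        elif key_u in DIMENSIONS:
            if value.startswith("{") and value.endswith("}"):
                toks = value[1:-1].split(",")
                bins = tuple(sorted({_label_to_bin(key_u, t, scheme)
                                     for t in toks}))
            elif (key_u in _NUMERIC_DIMS and "-" in value
                  and not value.startswith(">")):
                lo_s, _, hi_s = value.partition("-")
                try:
                    lo, hi = float(lo_s), float(hi_s)
                except ValueError:
                    raise QueryError(
                        f"bad numeric range {value!r} at position {pos}") from None
                bins = _range_to_bins(key_u, lo, hi, scheme)
            else:
                bins = (_label_to_bin(key_u, value, scheme),)
            constraints[key_u] = bins
        else:
            raise QueryError(f"unknown key {key!r} at position {pos}")
        pos += len(token)
    return QuerySpec(constraints=constraints, axes=axes, mode=mode,
                     symmetrize=symmetrize)
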