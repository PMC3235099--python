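# Methods

## The model

`foldcube` treats a protein chain as a set of residues stratified into
concentric solvent-accessibility shells, and a residue pair as a point in
an 8-dimensional discrete space: the two residue types, the shared shell,
the functional-atom distance, the two secondary-structure classes, the
chain length and the sequence separation.  Counting all pairs of a chain
collection over this space gives a sparse contingency tensor whose filled
cells are the realized packing arrangements and whose counts measure how
common each arrangement is.  Significance is assessed against a
composition-preserving null: the same chains with residue-type labels
permuted, which keeps all geometry and asks only "would this pair of
*types* appear here if types were assigned at random?".

Assumptions worth keeping in mind:

- **Globularity.** The shell picture (and the shell "thickness" computed
  as mean distance to the chain's geometric center per shell) treats the
  chain as roughly spherical; for elongated or multi-domain chains it is a
  coarse approximation.  Shells are defined purely by relative solvent
  accessibility, so binning itself does not depend on the spherical
  picture — only the thickness profile does.
- **Same-shell restriction.** Only pairs within one SA shell are counted.
  Pairs bridging neighbouring shells exist but are deliberately excluded
  to bound the combinatorics; queries can therefore never see them.
- **Per-chain analysis.** The unit is the single chain: the geometric
  center, chain length and all pairs are per chain, and inter-chain pairs
  are out of scope.  This matches a chain-culled input set; for a
  multi-chain file each selected chain is processed independently.

## Parameters and bin edges

All intervals are half-open, right-closed (lo < x ≤ hi), applied exactly
at the printed edges (a value exactly on an edge belongs to the bin ending
there):

- **SA** (12 bins): SA≤0, then 10 %-wide bins to 100, then SA>100.
  Relative SA = 100 · SASA / (maximal Gly-X-Gly tripeptide area of the
  residue type); values over 100 % occur (terminal or unusually exposed
  residues) and get their own bin, as does exactly 0 (fully buried).
- **D** (14 bins): D≤1.75 then 0.5 Å-wide bins up to 8.25 Å.  The pair
  criterion is strict: d < 8.25 Å.  There is no open top bin — a more
  distant pair is simply not an observation.
- **CL** (12 bins): 100-residue-wide bins to 1000, plus CL>1000.  CL≤0 is
  retained for table completeness but is provably empty (a validated chain
  has ≥1 residue); likewise SD bin "0" (a pair has two distinct
  positions).  Tests assert both stay empty.
- **SD** (6 bins): exact separations 0–4 and >4, computed on the
  *post-validation* consecutive residue index, not on author numbering
  with its gaps and insertion codes.
- **Functional atoms**: one or two designated side-chain atoms per type
  (Gly uses CA).  For two-atom groups the pair distance is the **minimum**
  over the 1–4 atom combinations — the closest-heavy-atom convention used
  for salt-bridge detection.
- **Reference areas**: the Chothia (1976) accessible surface areas of
  residue X in a Gly-X-Gly tripeptide, as tabulated in Creighton's
  *Proteins* (Ala 115 … Trp 255 Å²).  They live in
  `foldcube.constants.REFERENCE_AREAS` and can be swapped for another
  scale; changing them rescales relative SA and thus shell assignment.
- **Secondary structure**: DSSP 8-state codes reduced conventionally to 4
  classes (H,G,I → helix; E,B → strand; T,S → turn; everything else,
  including blank, → coil).

## Validation

A residue is retained only if it has CA coordinates, every functional atom
of its (annotation-supplied) type, a standard type, a parseable SS code
and SASA, and an annotation row matched by chain id + coordinate-file
residue number.  Everything else is discarded individually, with the rest
of the chain kept; a chain losing all residues is dropped with a warning.
Alternate conformations keep the first conformer; HETATM records and
waters are excluded.  Validation is idempotent.

## The shuffled reference

`shuffle_chain` permutes only the residue-type labels; each position keeps
its coordinates, SA value and SS class.  This is the minimal null model
that needs no invented geometry: pair existence depends only on positions
and shells, so the reference tensor has exactly the same total count as
the observed tensor, and its marginal over the two type dimensions equals
the observed marginal cell-by-cell — both useful invariants that the test
suite checks.  The stored relative SA is not recomputed for the new type's
reference area; the shell structure is a property of the position.  Ten
shuffles per chain are averaged by default; counts are persisted as the
integer sum plus the divisor so the average stays exact.  Seeding derives
one independent stream per (chain, shuffle) from the master seed via a
CRC of the chain's identity, so results do not depend on processing order.

## Queries

Projection sums counts over all non-display dimensions restricted to the
constraint subsets.  The **ratio is taken after projection**: a 2D ratio
map is (projected observed)/(projected reference) cell-by-cell on the 2D
aggregate, not a projection of per-cell ratios — aggregated ratios need no
weighting rule and match how 2D significance maps are read.  Ratio cells
with observed > 0 but reference = 0 are reported as masked-undefined
(exported as `NA`), never as an arbitrary large number; 0/0 is 0.
Normalization divides defined ratio values by their maximum, per displayed
selection (not globally), making plots comparable within one panel.
Symmetrized lookup adds each stored pair's AA/SS-swapped orientation,
counting self-symmetric cells once; storage itself is canonical (the
lower-sequence-index residue is AA1/SS1), so nothing is double-counted.

## Synthetic data

The fixture generator produces two kinds of chains:

- **Motif chains**: 8 residues; a designated pair placed at a seeded
  distance strictly inside the motif's characteristic window — disulphide
  Cys–Cys 1.80–2.24 Å (SD>4, buried shell), zinc-finger-like Cys–Cys
  3.81–4.24 Å and iron-sulfur-like 6.76–7.24 Å (sequence-local, buried),
  salt-bridge Lys–Asp 2.31–3.24 Å at 20–30 % SA with SD 4 (one helix
  turn), close Arg–Arg 3.31–3.74 Å at 10–20 % SA, and a repulsive Lys–Lys
  control at 12 Å that must contribute nothing.  Spacer residues are
  isolated (≥10 Å apart, different shell) so the designated pair is the
  only pair — which makes every downstream count exactly predictable.
- **Random chains**: uniform types, SS classes, SA in (0, 110], positions
  in a box with side 6·n^⅓ Å so a nontrivial fraction of pairs falls
  under the cutoff.  These feed the oracle-equivalence and conservation
  tests.

What the fixtures do **not** emulate: real backbone connectivity, sterics,
realistic SA/SS correlations, or realistic pair-count magnitudes.  Passing
tests therefore demonstrate the correctness of binning, enumeration,
accumulation, indexing and querying — not any biological conclusion, which
would require a large curated chain set.

## Numerical choices

- Bin lookup is `bisect_left` over the edge array, which implements
  right-closed intervals exactly, including values exactly at an edge.
- Coordinates round-trip through fixed-column PDB text at 1e-3 Å; tests
  compare at that tolerance.
- Distances are plain `numpy` Euclidean norms; the minimum over ≤4 atom
  combinations is exact.
- Degenerate inputs (empty residue, empty chain) raise typed errors;
  empty shells report an undefined (NaN) mean, never 0.
- The acceptance script uses 100 random chains of 2–50 residues and two
  motif fixtures; these sizes keep the whole run around a second while
  exercising every pipeline stage.

## Known limitations

- Genuine-HSSP parsing targets the standard fixed-column residue block;
  exotic header variants are untested against real archive files.
- No mmCIF input; no SASA computation from coordinates (accessibility is
  an input, as annotation); no inter-shell or inter-chain pairs;
  no statistical test beyond the observed/reference ratio.
- Residue numbers above 9999 cannot be encoded in the fixed-width pair
  identifier and raise an error rather than truncating.
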