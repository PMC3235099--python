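# foldcube

Hyperdimensional amino-acid pair packing statistics for protein structures.

Protein folds are stabilized by pairwise residue interactions — disulphide
bridges, salt bridges, hydrophobic contacts — whose character depends not
only on the two residue types but on where in the protein the pair sits and
how the residues are arranged.  `foldcube` describes every residue pair by
eight coordinates and counts pairs in a sparse 8-dimensional tensor:

| dim | meaning | bins |
|-----|---------|------|
| AA1, AA2 | residue types | 20 each (Ala … Val) |
| SA | shared solvent-accessibility shell (% of Gly-X-Gly maximal area) | 12 (SA≤0, 0<SA≤10, …, 90<SA≤100, SA>100) |
| D | functional-atom distance (Å) | 14 (D≤1.75, …, 7.75<D≤8.25) |
| SS1, SS2 | secondary structure | 4 each (helix, strand, turn, coil) |
| CL | chain length | 12 (CL≤0, 0<CL≤100, …, CL>1000) |
| SD | sequence distance | 6 (0, 1, 2, 3, 4, >4) |

for a total of 20·20·12·14·4·4·12·6 = 77,414,400 cells.  Two residues form
a pair when they belong to the same chain, fall in the same SA shell, and
their functional atoms (the side-chain tips between which distances are
measured: Cys SG, Lys NZ, Asp OD1/OD2, …) are closer than 8.25 Å.

Three things make the tensor useful:

- a **reference tensor** built from chains whose residue-type labels were
  randomly permuted within each chain (10 shuffles, averaged) — the null
  model of random packing at fixed composition.  The observed/reference
  **ratio** of any projection flags over-represented geometry: a value
  above 1 means the arrangement occurs more often than random relabelling
  would produce;
- a **query engine** that constrains any subset of the 8 dimensions and
  projects the rest onto 1–3 display axes, in absolute, reference, ratio
  or warp mode (warp: absolute counts as heights, normalized ratio as
  color);
- a **pair index** storing a 14-character identifier (`1ABC0102A1030B` =
  residues 102/chain A and 1030/chain B of structure 1ABC) for every
  counted pair, so any interesting cell can be mapped back to the concrete
  residue pairs and structures behind it.

It reads PDB coordinate files plus per-residue annotation (HSSP, or a
simple whitespace table) carrying residue type, DSSP secondary-structure
code and solvent-accessible surface area.

## Worked example

The package ships a synthetic-fixture generator (miniature chains with a
designated pair at prescribed geometry), so the pipeline can be exercised
without downloading structures:

```sh
foldcube fixtures --motif disulphide  --seed 1 --out data
foldcube fixtures --motif salt_bridge --seed 1 --out data
foldcube build --structures data --annotations data \
    --out run/cube --shuffles 10 --seed 7
# chains: 2  observations: 2  filled cells: 2
```

Two chains yield two pair observations (each motif chain contributes
exactly one pair).  Query the Cys–Cys pairs, displaying spatial distance
against sequence separation:

```sh
foldcube query --tensor run/cube --expr "AA1=CYS AA2=CYS axes=D,SD" --out cys.tsv
# selection total: 1
```

The exported table has its single count in the D bin `1.75<D<=2.25` at
sequence distance `>4` — the disulphide-bridge signature: covalently
bonded sulfurs ~2 Å apart, linking sequence-distant cysteines:

```
D\SD          0  1  2  3  4  >4
D<=1.75       0  0  0  0  0  0
1.75<D<=2.25  0  0  0  0  0  1
...
```

Back-map the cell to the concrete residues:

```sh
foldcube pairs --index run/cube --expr "AA1=CYS AA2=CYS" --out hits.tsv
# 1 pair(s) in 1 cell(s)
```

`hits.tsv` names the pair — residues 1 and 7 of chain A in synthetic
structure 0DSB — and `--selections` additionally writes viewer selection
commands for it.

Query syntax: `KEY=VALUE` tokens separated by spaces.  Constraints take a
single label (`AA1=LYS`, `SS1=helix`, `SD=>4`), a set (`AA1={ARG,LYS}`), or
a numeric range covering whole bins (`SA=20-40` → shells 20–30 and
30–40 %).  `axes=D,SA` picks 1–3 display dimensions,
`mode=absolute|reference|ratio|warp`, `symmetrize=on` adds the
AA1/AA2-swapped orientation of each stored pair (the homotypic diagonal is
counted once).

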