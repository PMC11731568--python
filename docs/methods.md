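# Methods

## The TSR representation

A molecule is reduced to an ordered atom list (a *selection*) and then to
the multiset of integer keys over all C(n, 3) atom triangles.  Three
selection modes exist and differ only in which atoms are taken and how
vertices are labelled:

| mode | atoms | vertex label |
|------|-------|--------------|
| `CA` | one Cα per standard residue of a chain | residue identity, the 20 standard residues numbered alphabetically by three-letter code (ALA = 1 … VAL = 20) |
| `COFACTOR` | all heavy atoms of one annotated ligand | chemical element (C = 1, N = 2, O = 3, S = 4, Mg = 5, P = 6, Fe = 7, then the remaining elements in atomic-number order) |
| `AA` | all heavy atoms of one amino acid | chemical element, as above |

Hydrogens never enter key generation (the element field decides; when it is
absent, a leading-H-after-digits name heuristic).  Waters are parsed and
flagged but excluded from selections; they are visible only to the
environment module.

### Vertex ordering

Vertices are sorted by descending integer label.  Ties among equal labels
are broken by descending distance to the triangle centroid, and residual
ties (e.g. an equilateral triangle of equal labels) by ascending input
index.  Because the first two criteria depend only on labels and internal
geometry, the resulting key multiset is invariant under rigid motion and
under permutation of atom input order; the third criterion can only be
reached when the triangle is geometrically symmetric, in which case every
choice yields the same binned key.  Both invariances are property-tested.

### Geometry, binning, encoding

*MaxDist* is the longest edge (Å).  *Theta* is the angle at the midpoint M
of the l₁–l₂ edge between M→l₃ and M→l₂; obtuse values are folded to
180° − θ, and exactly 90° is kept (it lands in the last Theta bin).
Triangles with coincident vertices, a vanishing median, or θ below 1e-9°
(collinear) are skipped and counted in a logged warning; all other
triangles contribute exactly one key, so with no degenerate input the total
key count equals C(n, 3).

Default bins, all configurable through `BinningConfig`:

* **Theta**: 30 equal-width bins over (0°, 90°] in every mode.  The
  historical boundary set for backbone keys is not public; equal-width
  bins are the reproducible choice, and every output file records the bin
  boundaries and config hash so keys are self-describing.
* **MaxDist**: `CA` 35 bins × 3 Å over (0, 105 Å] (long enough for a large
  single chain); `COFACTOR` 17 bins × 1 Å; `AA` 58 bins × 1 Å.
* **Overflow**: values beyond the last boundary fall into the last bin and
  values below the first into bin 1.  Chlorophyll tail atoms routinely
  exceed the 17 Å cofactor range, which is intended — the overflow bin
  absorbs them — but note this compresses resolution for very extended
  molecules; the tail filter (below) is the sharper tool.

The key integer is the mixed-radix pack
`((l₁−1)m² + (l₂−1)m + (l₃−1))·nθ·nd + (θbin−1)·nd + (dbin−1)` with
m = number of labels.  It is a bijection between valid tuples and a dense
integer range (tested exhaustively on small spaces), and `decode_key`
inverts it exactly.  Key integers are only meaningful **relative to one
config**: comparing key files produced under different configs is refused,
and absolute key values from other TSR implementations (with unpublished
bin boundaries or packing) will not match — set relationships and counts
are the comparable quantities.

### Filters and variants

* **Phytol-tail filter**: the packaged `PHYTOL_TAIL` preset removes
  chlorophyll tail carbons C6–C20 by atom name, restricting keys to the
  chlorin ring, whose conformation is the electron-transfer-relevant part.
* **Size-gap cutoff**: when set (20 Å is the conventional value), triangles
  with MaxDist above the cutoff are dropped before binning.  This is the
  filter interpretation of the size-gap idea: it removes the long-range
  triangles that dominate when structures of unequal size are compared.
* **Amino-acid grouping** (`CA` mode): an optional label remap applied
  before vertex ordering merges chemically similar residues —
  (Asp, Glu), (Asn, Gln), (Ser, Thr), (Lys, Arg), (Ile, Leu, Val),
  (Phe, Tyr, Trp) — each group taking the smallest member label.

## Similarity and key-set algebra

Generalized Jaccard, Σₖ min(f_a, f_b) / Σₖ max(f_a, f_b), is the
frequency-aware similarity used for proteins and cofactors; 1 − GJ is a
metric on multisets (property-tested on random triples).  The *Normalized*
Jaccard used for single amino acids is taken as the frequency-free set
Jaccard over key supports — the frequency-free reading is the natural
counterpart and is recorded in output metadata.  Key taxonomy: *distinct* =
|support|, *total* = Σ frequencies, *common* (of a group) = keys in every
member, *specific* (of a group against contrast groups) = keys in every
member of the group and in no member of any contrast group.  Venn regions
are computed on pooled (union) group supports by default; group aggregates
are reported as mean ± SD with 25/75 percentiles.  Pairwise aggregate
statistics use unordered pairs excluding self-pairs.

## Clustering and statistics

* **UPGMA** is implemented directly (O(n³), exact size-weighted average
  update) rather than through a library call because the contract requires
  a deterministic tie-break — smallest leaf-index pair — that off-the-shelf
  nearest-neighbour-chain implementations do not guarantee.  Heights are
  verified in tests against scipy's average linkage and against a
  brute-force cross-pair average oracle.  Dendrograms export to Newick with
  children ordered smallest-leaf-first.
* **Flat cuts** use the standard maxclust criterion on the merge tree; when
  scoring against ground-truth classes, k defaults to the number of
  classes.
* **Classical (Torgerson) MDS**: double-centering of squared distances and
  the top-dim spectral components; negative eigenvalues (non-Euclidean
  input) are truncated to zero with a warning.  Distance recovery on
  planted coordinates is exact to 1e-9.
* **ARI** comes from scikit-learn and is cross-checked against an
  exhaustive pair-counting implementation for n ≤ 12.
* **Two-group test**: Welch's unequal-variance t-test (the safer default
  when only "t-test" is specified), two-sided, with the conventional
  star annotation at p < 0.05 / 0.01 / 0.001.

## Baselines

* **USR**: 12 descriptors — mean, population SD and the signed cube root of
  the third central moment (kept in Å for unit consistency) of the
  atom-distance distributions about the centroid (ctd), the atom closest to
  it (cst), the atom farthest from it (fct) and the atom farthest from fct
  (ftf).  Ties for the reference atoms are broken by input order.
  Similarity is the standard inverse mean Manhattan score
  1 / (1 + mean |Δ|).  Protein-level USR uses the same Cα selection handed
  to TSR.
* **RMSD**: Kabsch superposition (SVD with determinant correction, proper
  rotations only).  Atom correspondence defaults to matching by atom name —
  exact for chemically identical cofactors or residues — with positional
  (`by-order`) and exhaustive (`brute-force`, ≤ 8 atoms, used as the test
  oracle) alternatives.  Protein-level RMSD between non-identical sequences
  is out of scope; externally produced distance matrices can be fed to the
  clustering stage as CSV.

## Structure input

gemmi parses PDB and mmCIF; model 1 only.  Alternate locations resolve to
the highest-occupancy conformer, ties to the alphabetically first altloc
code.  Residue numbering is taken verbatim from the source file.  ATOM and
HETATM records are both kept; malformed coordinate lines fail with the line
number.

## Synthetic fixtures: what they do and do not show

`make_toy_protein` emits an ideal helix Cα trace (rise 1.5 Å, 100° turn,
radius 2.3 Å, configurable residue pattern); `make_toy_cofactor` a planar
25-heavy-atom macrocycle with chlorophyll-style atom names and an optional
C6–C20 tail reaching past 20 Å (small irregular radial/axial offsets keep
every atom triple non-collinear so triangle counts are exactly C(n, 3));
`jitter_family` makes seed-deterministic Gaussian-perturbed copies.  These
exercise every selection filter, the invariances, bin overflow, the
size-gap cutoff and clustering recovery, but they are not chemistry: bond
lengths, planarity constraints and real conformational variability are not
modelled.  Passing the desk suite therefore demonstrates algorithmic
correctness (counting, invariance, metric properties, oracle agreement),
not biological conclusions about real PS I structures; the reference-entry
workflow in `examples/accession_cofactor_analysis.py` and the accession
tests exist for that and require downloading the entries.

## Verification problem sizes

The test-suite and acceptance-script computations run at deliberately small
sizes chosen so exhaustive oracles stay exact and fast: 40-atom cofactor
and 12–15-residue helix fixtures (≤ 9880 triangles), exhaustive
encode/decode over a 4500-tuple space, brute-force RMSD at 7 atoms, UPGMA
and ARI oracles at n ≤ 12, and 1000-triple metric sampling.  The pipeline
itself is vectorised and chunked (500k triangles per chunk) and handles
selections of a few hundred atoms comfortably; all-triangle key generation
for a full ~750-residue chain (~7 × 10⁷ triangles) is minutes-scale work
and best run with `records=False`.

## Known limitations

* Absolute key integers are config-relative by design; there is no
  compatibility with unpublished historical key values.
* The Theta bin boundaries and the CA-mode MaxDist boundaries are
  equal-width defaults, not the historical sets; binning-sensitive counts
  (e.g. distinct-common totals) shift with the config, which is why every
  artifact carries the config hash.
* The 3.5 Å heavy-atom criterion for binding-site contacts is a geometric
  proxy; manually curated contact tables may differ at the margin, and such
  discrepancies are reported, not forced.
* `rmsd_superposed` with brute-force matching is factorial and capped at
  8 atoms; by-name matching requires unique atom names per selection.
* No symmetry-mate expansion, assembly building, sequence alignment,
  hydrogen-bond geometry or redox-potential estimation.
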