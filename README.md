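# tsrkit

Alignment-free comparison of molecular 3D structures with **Triangular
Spatial Relationship (TSR) keys**, built for — but not limited to — the
analysis of photosystem I (PS I) electron-transfer cofactors and their
binding sites.

Classical structure comparison either superposes matched atoms (RMSD,
TM-align) or summarises global shape (USR).  The TSR approach instead
enumerates **every triangle** of a selected atom set and encodes each one as
a single integer, so a molecule becomes a multiset of integer keys.  Keys
are exactly invariant under rotation, translation and atom input order, can
be compared without any alignment, and — unlike a distance or a shape
moment — can be **mapped back to the three atoms** that produced them, which
is what makes "this substructure occurs in every P700 chlorophyll but no
A<sub>0</sub> chlorophyll" a computable statement.

## The key construction

For a triangle with vertices carrying integer labels (residue identity in
`CA` mode; chemical element in `COFACTOR`/`AA` modes):

1. Order the vertices (l₁, l₂, l₃) by descending label; break label ties by
   descending distance to the triangle centroid, then by input index.
2. Compute **MaxDist** (longest edge, Å) and **Theta**: the acute angle at
   the midpoint M of the l₁–l₂ edge between M→l₃ and M→l₂, folded into
   (0°, 90°].
3. Bin both (defaults: 30 equal Theta bins; 35 × 3 Å MaxDist bins for `CA`,
   17 × 1 Å for `COFACTOR`, 58 × 1 Å for `AA`) and pack everything into one
   integer:

   ```
   key = ((l₁−1)·m² + (l₂−1)·m + (l₃−1)) · nθ·nd + (θbin−1)·nd + (dbin−1)
   ```

Similarity between molecules is the **Generalized Jaccard** coefficient of
their key-frequency vectors, Σₖ min(f_a, f_b) / Σₖ max(f_a, f_b) (the
frequency-free set Jaccard is used for single amino acids).  1 − similarity
feeds average-linkage (UPGMA) clustering, classical MDS, and adjusted-Rand
scoring against functional classes.  USR shape descriptors and Kabsch
superposition RMSD are included as baselines, and a key-set algebra module
mines distinct/total/common/specific keys and Venn regions between groups.

The packaged annotation table maps the nine reference PS I entries (1JB0,
5OY0, 6HQB, 6JO6, 6KMW, 6KMX, 6PNJ, 7COY, 5ZJI) to the chain/residue of
each electron-transfer chlorophyll role (P700, A₋₁, A₀, A_C, both branches)
and its axial ligand.

## Worked example

`examples/jitter_clustering.py` builds two helix families (different turn
angle and residue pattern), jitters each template six times with σ = 0.05 Å,
and runs the full pipeline:

```
$ python examples/jitter_clustering.py
mean within-family similarity : 0.654
mean across-family similarity : 0.000
ARI of the k=2 cut            : 1.000
(((((famA_0:0.273245,famA_2:0.273245):0.0493344,...
```

Within-family Generalized Jaccard stays high because 0.05 Å of jitter
rarely pushes a triangle across a bin boundary; across-family similarity is
zero because the residue labels differ, and the k = 2 dendrogram cut
recovers the families perfectly (ARI 1.0).  The other scripts in
`examples/` cover key generation and decoding (`cofactor_keys.py`),
common/specific key mining (`key_mining.py`), the USR/RMSD baselines
(`baseline_comparison.py`), binding-site contact shells
(`binding_site_contacts.py`) and the network-requiring reference-entry
analysis (`accession_cofactor_analysis.py`).

A thin CLI mirrors the library:

```bash
tsrkit fixtures --kind toy_cofactor --with-tail --out cla.pdb
tsrkit keygen cla.pdb --mode COFACTOR --role P700_A --annotations ann.tsv --out keys/
tsrkit similarity keys/*.keys.tsv --out sim.csv
tsrkit cluster --similarity sim.csv --classes classes.csv --out clust
```

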