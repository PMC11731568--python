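"""Cluster two families of perturbed helices with the TSR pipeline.

Two distinct helix templates (different turn angle and residue pattern) each
produce six copies with 0.05 A Gaussian coordinate jitter.  Keys ->
Generalized Jaccard similarity -> UPGMA -> flat cut at k=2 -> adjusted Rand
index against the true family labels.  ARI 1.0 means the dendrogram separates
the families perfectly.
"""

import tsrkit as tk
from tsrkit.structure_io import MoleculeSelection, Provenance

config = tk.default_config("CA")
templates = {
    "famA": tk.make_toy_protein(15),
    "famB": tk.make_toy_protein(15, turn=122.0, pattern=("LEU", "SER", "PHE")),
}

key_vectors, truth = [], []
for fam_idx, (family, text) in enumerate(sorted(templates.items())):
    template = tk.select_calpha(tk.read_structure(text), "A")
    for i, member in enumerate(tk.jitter_family(template, 6, sigma=0.05, seed=fam_idx)):
        member = MoleculeSelection(
            member.atoms, Provenance("TOY", "A", "helix", f"{family}_{i}"), "CA"
        )
        kv, _ = tk.generate_keys(member, config, records=False)
        key_vectors.append(kv)
        truth.append(family)

sim = tk.similarity_matrix(key_vectors)
tree = tk.average_linkage(tk.to_distance(sim), [kv.label for kv in key_vectors])
flat = tk.cut_clusters(tree, 2)
ari = tk.adjusted_rand_index(truth, flat)

within = [sim.values[i, j] for i in range(6) for j in range(i + 1, 6)]
across = [sim.values[i, j] for i in range(6) for j in range(6, 12)]
print(f"mean within-family similarity : {sum(within) / len(within):.3f}")
print(f"mean across-family similarity : {sum(across) / len(across):.3f}")
print(f"ARI of the k=2 cut            : {ari:.3f}")
print(tree.to_newick())
# Within-family similarities stay high because 0.05 A jitter rarely moves a
# triangle across a bin boundary; across-family similarity collapses because
# the residue labels (and hence the keys) barely overlap.
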