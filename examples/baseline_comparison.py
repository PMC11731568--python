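"""Compare the TSR pipeline with the USR and RMSD baselines.

All three methods score the same task: separating two jittered helix
families.  TSR uses Generalized Jaccard over key multisets, USR uses the
inverse-Manhattan score over 12 shape moments, and RMSD uses Kabsch
superposition with by-order correspondence.  Each distance matrix is
clustered with UPGMA and cut at k=2; the adjusted Rand index against the
true families is the score.
"""

import numpy as np

import tsrkit as tk
from tsrkit.structure_io import MoleculeSelection, Provenance

config = tk.default_config("CA")
templates = {
    "famA": tk.make_toy_protein(15),
    "famB": tk.make_toy_protein(15, turn=112.0),
}

selections, truth = [], []
for fam_idx, (family, text) in enumerate(sorted(templates.items())):
    template = tk.select_calpha(tk.read_structure(text), "A")
    for i, member in enumerate(tk.jitter_family(template, 5, sigma=0.1, seed=fam_idx)):
        selections.append(
            MoleculeSelection(
                member.atoms, Provenance("TOY", "A", "helix", f"{family}_{i}"), "CA"
            )
        )
        truth.append(family)
n = len(selections)


def ari_from_distance(dist):
    result = tk.average_linkage(dist, [s.provenance.label for s in selections])
    return tk.adjusted_rand_index(truth, tk.cut_clusters(result, 2))


# TSR
kvs = [tk.generate_keys(s, config, records=False)[0] for s in selections]
tsr_ari = ari_from_distance(tk.to_distance(tk.similarity_matrix(kvs)))

# USR
descs = [tk.usr_descriptors(s) for s in selections]
usr_dist = np.zeros((n, n))
for i in range(n):
    for j in range(i + 1, n):
        usr_dist[i, j] = usr_dist[j, i] = 1.0 - tk.usr_similarity(descs[i], descs[j])
usr_ari = ari_from_distance(usr_dist)

# RMSD (identical residue counts, so by-order correspondence is exact)
rmsd_dist = np.zeros((n, n))
for i in range(n):
    for j in range(i + 1, n):
        rmsd_dist[i, j] = rmsd_dist[j, i] = tk.rmsd_superposed(
            selections[i], selections[j], "by-order"
        )
rmsd_ari = ari_from_distance(rmsd_dist)

print(f"TSR  ARI: {tsr_ari:.3f}")
print(f"USR  ARI: {usr_ari:.3f}")
print(f"RMSD ARI: {rmsd_ari:.3f}")
# On templates this different, all methods should reach ARI 1.0; the methods
# diverge on subtler contrasts (e.g. same shape, different residue identity,
# which USR and RMSD cannot see at all but TSR labels can).
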