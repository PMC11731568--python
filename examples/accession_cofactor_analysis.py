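"""Reference photosystem I cofactor analysis (requires network access).

Downloads the five reference PS I entries (1JB0, 5OY0, 6JO6, 6PNJ, 5ZJI),
selects the 40 annotated electron-transfer chlorophylls (P700, accessory
A_-1, acceptor A_0 and connecting A_C on both branches) from the packaged
annotation table, and computes:

* average distinct / total cofactor keys per pigment;
* the fraction of the pooled key union shared by all four cofactor classes;
* the number of keys common to every one of the 40 pigments;
* tail-filtered TSR clustering of the redox cofactors (P700 / A_-1 / A_0)
  with its ARI against the functional classes, next to the USR baseline.

Structures are cached under ~/.cache/tsrkit after the first run.
"""

import numpy as np

import tsrkit as tk
from tsrkit.structure_io import MoleculeSelection, Provenance

ENTRIES = ("1JB0", "5OY0", "6JO6", "6PNJ", "5ZJI")
CLASSES = {
    "P700": ("P700_A", "P700_B"),
    "A_-1": ("A_-1A", "A_-1B"),
    "A_0": ("A_0A", "A_0B"),
    "A_C": ("A_CA", "A_CB"),
}

annotations = tk.load_cofactor_annotations()
config = tk.default_config("COFACTOR")

selections = {}
for entry in ENTRIES:
    model = tk.read_structure(tk.fetch_structure(entry))
    for row in annotations:
        if row.pdb_id == entry:
            selections[(entry, row.role)] = tk.select_cofactor(model, row)
print(f"selected {len(selections)} pigments from {len(ENTRIES)} entries")

kvs = {k: tk.generate_keys(s, config, records=False)[0] for k, s in selections.items()}
totals = [kv.total() for kv in kvs.values()]
distincts = [kv.distinct() for kv in kvs.values()]
print(f"average keys per pigment: {np.mean(distincts):.0f} distinct / "
      f"{np.mean(totals):.0f} total")

groups = [
    tk.KeyGroup(name, [kvs[k] for k in kvs if k[1] in roles])
    for name, roles in CLASSES.items()
]
regions = tk.venn_regions(groups, "group-union")
union = sum(regions.values())
shared = regions["&".join(g.name for g in groups)]
print(f"keys shared by all four classes: {shared} of {union} "
      f"({100.0 * shared / union:.1f}% of the union)")

everyone = tk.KeyGroup("all", list(kvs.values()))
print(f"keys common to every pigment: {len(everyone.intersection_support())}")

# tail-filtered clustering of the redox cofactors
redox = [(k, s) for k, s in selections.items() if not k[1].startswith("A_C")]
truth = [k[1].rstrip("AB").rstrip("_") for k, _ in redox]
fkvs = []
for (entry, role), sel in redox:
    ring = tk.filter_atoms(sel, tk.PHYTOL_TAIL)
    ring = MoleculeSelection(
        ring.atoms,
        Provenance(entry, sel.provenance.chain, sel.provenance.span, f"{entry}_{role}"),
        "COFACTOR",
    )
    fkvs.append(tk.generate_keys(ring, config, records=False)[0])
sim = tk.similarity_matrix(fkvs)
tree = tk.average_linkage(tk.to_distance(sim), [kv.label for kv in fkvs])
tsr_ari = tk.adjusted_rand_index(truth, tk.cut_clusters(tree, 3))
print(f"tail-filtered TSR clustering ARI (P700/A_-1/A_0, k=3): {tsr_ari:.3f}")

descs = [tk.usr_descriptors(s) for _, s in redox]
n = len(descs)
usr_dist = np.zeros((n, n))
for i in range(n):
    for j in range(i + 1, n):
        usr_dist[i, j] = usr_dist[j, i] = 1.0 - tk.usr_similarity(descs[i], descs[j])
usr_ari = tk.adjusted_rand_index(
    truth,
    tk.cut_clusters(tk.average_linkage(usr_dist, [kv.label for kv in fkvs]), 3),
)
print(f"USR clustering ARI on the same cofactors: {usr_ari:.3f}")
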