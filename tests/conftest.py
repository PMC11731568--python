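"""Shared fixtures: small synthetic structures and key-vector builders."""

from __future__ import annotations

import numpy as np
import pytest

import tsrkit as tk
from tsrkit.structure_io import MoleculeSelection, Provenance


def build_pdb(residues, chain="A", hetatm=False) -> str:
    """PDB text from [(res_name, res_seq, [(atom_name, element, xyz), ...]), ...]."""
    lines = []
    serial = 0
    record = "HETATM" if hetatm else "ATOM  "
    for res_name, res_seq, atoms in residues:
        for name, element, xyz in atoms:
            serial += 1
            padded = name if len(name) >= 4 else f" {name:<3s}"
            lines.append(
                f"{record}{serial:5d} {padded:<4.4s} {res_name:<3.3s} {chain:1s}"
                f"{res_seq:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"  1.00  0.00          {element:>2.2s}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


TRP_ATOMS = [
    ("N", "N", (1.458, 0.000, 0.000)),
    ("CA", "C", (0.000, 0.000, 0.000)),
    ("C", "C", (-0.551, 1.420, 0.000)),
    ("O", "O", (-1.760, 1.600, 0.100)),
    ("CB", "C", (-0.540, -0.760, -1.200)),
    ("CG", "C", (-0.300, -2.230, -1.210)),
    ("CD1", "C", (0.900, -2.850, -1.000)),
    ("CD2", "C", (-1.300, -3.250, -1.400)),
    ("NE1", "N", (0.720, -4.210, -1.100)),
    ("CE2", "C", (-0.620, -4.500, -1.350)),
    ("CE3", "C", (-2.700, -3.230, -1.600)),
    ("CZ2", "C", (-1.200, -5.770, -1.500)),
    ("CZ3", "C", (-3.280, -4.490, -1.750)),
    ("CH2", "C", (-2.500, -5.750, -1.700)),
]

GLY_ATOMS = [
    ("N", "N", (1.458, 0.000, 0.000)),
    ("CA", "C", (0.000, 0.000, 0.000)),
    ("C", "C", (-0.551, 1.420, 0.000)),
    ("O", "O", (-1.760, 1.600, 0.100)),
]


@pytest.fixture
def trp_model():
    return tk.read_structure(build_pdb([("TRP", 7, TRP_ATOMS)]))


@pytest.fixture
def toy_cofactor_sel():
    model = tk.read_structure(tk.make_toy_cofactor())
    res = model.chains["A"][0]
    return MoleculeSelection(
        res.heavy_atoms(), Provenance("TOY", "A", "CLA901", "toy"), "COFACTOR"
    )


@pytest.fixture
def toy_cofactor_tail_sel():
    model = tk.read_structure(tk.make_toy_cofactor(with_tail=True))
    res = model.chains["A"][0]
    return MoleculeSelection(
        res.heavy_atoms(), Provenance("TOY", "A", "CLA901", "toy_tail"), "COFACTOR"
    )


@pytest.fixture
def toy_protein_sel():
    model = tk.read_structure(tk.make_toy_protein(12))
    return tk.select_calpha(model, "A")


def make_kv(counts, label="kv", mode="COFACTOR", config_hash="testcfg"):
    """KeyVector literal for set-algebra tests."""
    return tk.KeyVector(
        provenance=Provenance("T", "A", label, label),
        mode=mode,
        config_hash=config_hash,
        counts=dict(counts),
    )


def rotate_translate(coords: np.ndarray, seed: int) -> np.ndarray:
    """Random proper rotation + translation, seed-deterministic."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(scale=10.0, size=3)
    return coords @ Q.T + t
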