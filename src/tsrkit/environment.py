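"""Cofactor local-environment statistics.

Distances are computed between heavy atoms only (the reference structures
carry no hydrogens).  A residue "contacts" a cofactor when any of its heavy
atoms lies within the cutoff (3.5 A by default) of any cofactor heavy atom;
waters are excluded from the residue contact list but can be reported
separately (the accessory-chlorophyll axial water sits in that shell).
Aromatic residues are PHE, TYR and TRP.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import MoleculeSelection, StructureModel

__all__ = [
    "ContactReport",
    "AROMATIC_RESIDUES",
    "min_distance",
    "contact_residues",
    "aromatic_stats",
    "chain_composition",
]

AROMATIC_RESIDUES = frozenset({"PHE", "TYR", "TRP"})
DEFAULT_CONTACT_CUTOFF = 3.5


def min_distance(a: MoleculeSelection, b: MoleculeSelection) -> float:
    """Shortest distance over all cross atom pairs of two selections (A)."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty selection")
    return float(cdist(a.coords, b.coords).min())


@dataclass
class ContactReport:
    """Residues within a cutoff of a cofactor, with per-residue minimum distances."""

    role: str
    cutoff: float
    contacts: list[tuple[str, int, str, float]]  # (chain, res_seq, res_name, min dist)
    waters: list[tuple[str, int, float]] = field(default_factory=list)

    @property
    def aromatic_count(self) -> int:
        return sum(1 for _, _, name, _ in self.contacts if name in AROMATIC_RESIDUES)

    @property
    def aromatic_fraction(self) -> float:
        return self.aromatic_count / len(self.contacts) if self.contacts else 0.0

    def residue_tags(self) -> list[str]:
        return [f"{chain}-{name}{seq}" for chain, seq, name, _ in self.contacts]

    def to_json(self) -> str:
        return json.dumps(
            {
                "role": self.role,
                "cutoff": self.cutoff,
                "contacts": [
                    {"chain": c, "res_seq": s, "res_name": n, "min_dist": round(d, 3)}
                    for c, s, n, d in self.contacts
                ],
                "waters": [
                    {"chain": c, "res_seq": s, "min_dist": round(d, 3)}
                    for c, s, d in self.waters
                ],
                "aromatic_count": self.aromatic_count,
                "aromatic_fraction": round(self.aromatic_fraction, 4),
            },
            indent=2,
        )


def contact_residues(
    model: StructureModel,
    cofactor: MoleculeSelection,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> ContactReport:
    """Protein residues with any heavy atom within *cutoff* of the cofactor.

    Standard amino acids only; waters within the shell are reported in the
    separate ``waters`` list.  The cofactor's own residue is never a contact.
    """
    if not any(True for _ in model.residues()):
        raise ValueError("empty model")
    cof_coords = cofactor.coords
    cof_key = {(a.chain_id, a.res_seq, a.res_name) for a in cofactor.atoms}
    contacts: list[tuple[str, int, str, float]] = []
    waters: list[tuple[str, int, float]] = []
    for res in model.residues():
        if (res.chain_id, res.res_seq, res.res_name) in cof_key:
            continue
        if not (res.is_standard or res.is_water):
            continue
        heavy = res.heavy_atoms()
        if not heavy:
            continue
        coords = np.array([a.coords for a in heavy])
        dmin = float(cdist(coords, cof_coords).min())
        if dmin <= cutoff:
            if res.is_water:
                waters.append((res.chain_id, res.res_seq, dmin))
            else:
                contacts.append((res.chain_id, res.res_seq, res.res_name, dmin))
    contacts.sort(key=lambda c: (c[0], c[1]))
    waters.sort(key=lambda w: (w[0], w[1]))
    return ContactReport(
        role=cofactor.provenance.label,
        cutoff=cutoff,
        contacts=contacts,
        waters=waters,
    )


def aromatic_stats(report: ContactReport) -> tuple[int, float]:
    """(aromatic contact count, aromatic fraction of all contacts)."""
    return report.aromatic_count, report.aromatic_fraction


def chain_composition(model: StructureModel, chain: str) -> dict[str, dict[str, float]]:
    """Counts and fractions of the 20 standard residue types in one chain."""
    residues = [r for r in model.chain(chain) if r.is_standard]
    if not residues:
        raise ValueError(f"chain {chain} contains no standard residues")
    counts: dict[str, int] = {}
    for res in residues:
        counts[res.res_name] = counts.get(res.res_name, 0) + 1
    total = len(residues)
    return {
        name: {"count": count, "fraction": count / total}
        for name, count in sorted(counts.items())
    }
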