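"""Baseline shape comparators: USR descriptors and superposition RMSD.

Ultrafast Shape Recognition (USR) summarises a molecule by the first three
moments (mean, standard deviation, signed cube root of the third central
moment) of the atom-distance distributions about four reference points: the
centroid (ctd), the atom closest to it (cst), the atom farthest from it
(fct) and the atom farthest from fct (ftf) — 12 numbers in total, invariant
under rigid motion.  Pairwise USR similarity is the standard inverse mean
Manhattan score 1 / (1 + mean |d1_i - d2_i|).

RMSD uses the Kabsch algorithm (proper rotation + translation, via SVD) and
a chosen atom correspondence: by atom name (exact for chemically identical
molecules), by input order, or — for up to 8 atoms — a brute-force search
over all one-to-one matchings, minimising the superposed RMSD.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .structure_io import MoleculeSelection

__all__ = [
    "UsrDescriptor",
    "usr_descriptors",
    "usr_similarity",
    "kabsch_rmsd",
    "rmsd_superposed",
]

_BRUTE_FORCE_LIMIT = 8


@dataclass(frozen=True)
class UsrDescriptor:
    """12-number USR shape descriptor (three moments x four reference points)."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != 12:
            raise ValueError("USR descriptor must contain 12 values")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def _moments(dists: np.ndarray) -> tuple[float, float, float]:
    mu = float(dists.mean())
    sd = float(dists.std(ddof=0))
    third = float(np.mean((dists - mu) ** 3))
    return mu, sd, float(np.cbrt(third))


def usr_descriptors(selection: MoleculeSelection | np.ndarray) -> UsrDescriptor:
    """USR descriptor of a selection (or raw (n, 3) coordinate array).

    Ties for the closest/farthest reference atoms are broken by input order;
    a zero-variance distance distribution yields sd 0 and skew term 0.
    """
    coords = selection if isinstance(selection, np.ndarray) else selection.coords
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) < 2:
        raise ValueError("need an (n >= 2, 3) coordinate array")
    ctd = coords.mean(axis=0)
    d_ctd = np.linalg.norm(coords - ctd, axis=1)
    cst = coords[int(np.argmin(d_ctd))]
    fct = coords[int(np.argmax(d_ctd))]
    d_fct = np.linalg.norm(coords - fct, axis=1)
    ftf = coords[int(np.argmax(d_fct))]
    values: list[float] = []
    for ref in (ctd, cst, fct, ftf):
        values.extend(_moments(np.linalg.norm(coords - ref, axis=1)))
    return UsrDescriptor(values=tuple(values))


def usr_similarity(d1: UsrDescriptor, d2: UsrDescriptor) -> float:
    """Inverse mean Manhattan USR score in (0, 1]; 1 iff identical descriptors."""
    diff = np.abs(d1.as_array() - d2.as_array()).mean()
    return 1.0 / (1.0 + diff)


# ---------------------------------------------------------------------------
# RMSD


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between two equally-sized point sets in the given order.

    Optimal translation (centroid alignment) and proper rotation (Kabsch via
    SVD with determinant correction — no reflections).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    H = ac.T @ bc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = (R @ ac.T).T - bc
    return float(np.sqrt((diff ** 2).sum() / len(a)))


def _match_by_name(a: MoleculeSelection, b: MoleculeSelection):
    names_a = [atom.atom_name for atom in a.atoms]
    names_b = [atom.atom_name for atom in b.atoms]
    for label, names in (("first", names_a), ("second", names_b)):
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise ValueError(
                f"by-name correspondence needs unique atom names; {label} "
                f"selection repeats {sorted(dup)}"
            )
    only_a = set(names_a) - set(names_b)
    only_b = set(names_b) - set(names_a)
    if only_a or only_b:
        raise ValueError(
            "atom-name mismatch between selections: "
            f"only in first {sorted(only_a)}, only in second {sorted(only_b)}"
        )
    order = sorted(names_a)
    ia = [names_a.index(n) for n in order]
    ib = [names_b.index(n) for n in order]
    return a.coords[ia], b.coords[ib]


def rmsd_superposed(
    a: MoleculeSelection,
    b: MoleculeSelection,
    correspondence: str = "by-atom-name",
) -> float:
    """Superposed RMSD between two selections under a chosen correspondence.

    ``by-atom-name`` (default) pairs atoms with equal names; ``by-order``
    pairs them positionally; ``brute-force`` minimises over all one-to-one
    matchings (selections of at most 8 atoms — factorial cost, intended as an
    oracle for small molecules).
    """
    if len(a) != len(b):
        raise ValueError(f"atom counts differ: {len(a)} vs {len(b)}")
    if correspondence == "by-atom-name":
        ca, cb = _match_by_name(a, b)
        return kabsch_rmsd(ca, cb)
    if correspondence == "by-order":
        return kabsch_rmsd(a.coords, b.coords)
    if correspondence == "brute-force":
        if len(a) > _BRUTE_FORCE_LIMIT:
            raise ValueError(
                f"brute-force matching is limited to {_BRUTE_FORCE_LIMIT} atoms"
            )
        ca, cb = a.coords, b.coords
        best = np.inf
        for perm in itertools.permutations(range(len(a))):
            best = min(best, kabsch_rmsd(ca, cb[list(perm)]))
        return float(best)
    raise ValueError(f"unknown correspondence {correspondence!r}")
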