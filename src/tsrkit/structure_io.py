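"""Structure reading and atom-subset selection.

Parsing of PDB/mmCIF is delegated to :mod:`gemmi`; this module flattens model
1 of a structure into a light chain -> residue -> atom hierarchy, resolves
alternate conformations (highest occupancy wins, ties go to the
alphabetically first altloc code), and builds the ordered, provenance-tagged
atom lists (:class:`MoleculeSelection`) that every key generator consumes:

* ``CA`` selections — one C-alpha per residue of a protein chain;
* ``COFACTOR`` selections — all heavy atoms of an annotated ligand
  (e.g. a chlorophyll of the PS I electron-transfer chain);
* ``AA`` selections — all heavy atoms of a single amino acid.

The packaged cofactor annotation table maps the nine reference photosystem I
entries (1JB0, 5OY0, 6HQB, 6JO6, 6KMW, 6KMX, 6PNJ, 7COY, 5ZJI) to the chain,
residue number, residue name and axial ligand of each electron-transfer
chlorophyll role (P700, accessory A_-1, primary acceptor A_0, connecting A_C,
on both the A and B branches).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Residue",
    "StructureModel",
    "Provenance",
    "MoleculeSelection",
    "CofactorAnnotation",
    "read_structure",
    "select_calpha",
    "select_cofactor",
    "select_residue",
    "filter_atoms",
    "selection_to_pdb",
    "load_cofactor_annotations",
    "STANDARD_AMINO_ACIDS",
    "WATER_NAMES",
]

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure or selection."""

    serial: int
    atom_name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    coords: tuple[float, float, float]
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")

    @property
    def is_hydrogen(self) -> bool:
        el = self.element.strip().upper()
        if el:
            return el in ("H", "D")
        # name heuristic: strip leading digits, then a leading H means hydrogen
        name = self.atom_name.lstrip("0123456789")
        return name[:1].upper() == "H"


@dataclass
class Residue:
    res_name: str
    res_seq: int
    chain_id: str
    is_hetero: bool
    atoms: list[AtomRecord]

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES

    @property
    def is_standard(self) -> bool:
        return self.res_name in STANDARD_AMINO_ACIDS

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class StructureModel:
    """Model 1 of a parsed structure: chains -> residues -> atoms."""

    source_id: str
    chains: dict[str, list[Residue]]

    def chain(self, chain_id: str) -> list[Residue]:
        if chain_id not in self.chains:
            raise KeyError(
                f"chain {chain_id!r} not in {self.source_id} "
                f"(available: {sorted(self.chains)})"
            )
        return self.chains[chain_id]

    def find_residue(self, chain_id: str, res_seq: int) -> Residue | None:
        for res in self.chain(chain_id):
            if res.res_seq == res_seq:
                return res
        return None

    def residues(self):
        for residues in self.chains.values():
            yield from residues


@dataclass(frozen=True)
class Provenance:
    """Where a selection came from: entry, chain, residue span, role tag."""

    source_id: str
    chain: str
    span: str
    role: str = ""

    @property
    def label(self) -> str:
        return self.role or f"{self.source_id}:{self.chain}:{self.span}"


@dataclass
class MoleculeSelection:
    """Ordered atom list handed to a key generator.

    Atom order is deterministic (file order after altloc resolution).  CA
    selections contain exactly one atom per residue, all named ``CA``;
    COFACTOR and AA selections contain no hydrogens.
    """

    atoms: list[AtomRecord]
    provenance: Provenance
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in ("CA", "COFACTOR", "AA"):
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if self.mode == "CA":
            bad = [a for a in self.atoms if a.atom_name != "CA"]
            if bad:
                raise ValueError("CA selection contains non-CA atoms")
        else:
            if any(a.is_hydrogen for a in self.atoms):
                raise ValueError(f"{self.mode} selection contains hydrogens")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) float array of atom coordinates in A."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, role: str | None = None) -> "MoleculeSelection":
        """Copy of this selection with replaced coordinates (same atoms)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            replace(a, coords=tuple(float(x) for x in xyz))
            for a, xyz in zip(self.atoms, coords)
        ]
        prov = self.provenance
        if role is not None:
            prov = replace(prov, role=role)
        return MoleculeSelection(atoms=atoms, provenance=prov, mode=self.mode)


@dataclass(frozen=True)
class CofactorAnnotation:
    """One row of the cofactor table: a role mapped to a ligand and its axial ligand."""

    pdb_id: str
    role: str
    chain: str
    res_seq: int
    res_name: str
    axial_chain: str = ""
    axial_res: str = ""


# ---------------------------------------------------------------------------
# reading


def _validate_pdb_text(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise ValueError(f"malformed coordinate line {lineno}: too short")
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError as exc:
                raise ValueError(f"malformed coordinate line {lineno}: {line!r}") from exc


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, tie -> first altloc code."""
    best: dict[str, AtomRecord] = {}
    order: list[str] = []
    for atom in atoms:
        key = atom.atom_name
        if key not in best:
            best[key] = atom
            order.append(key)
        else:
            cur = best[key]
            if (atom.occupancy, _neg_altloc(atom)) > (cur.occupancy, _neg_altloc(cur)):
                best[key] = atom
    return [best[k] for k in order]


def _neg_altloc(atom: AtomRecord):
    # sortable helper: higher is better, so invert the altloc code ordering
    return tuple(-ord(c) for c in (atom.altloc or "~"))


def read_structure(source: str | Path, format: str = "pdb") -> StructureModel:
    """Parse a structure from a file path or raw text.

    Only model 1 is used.  All ATOM and HETATM records are retained (waters
    included, flagged via :attr:`Residue.is_water`); alternate locations are
    resolved to the highest-occupancy conformer.
    """
    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unknown format {format!r}")
    text: str | None = None
    source_id = ""
    if isinstance(source, Path) or "\n" not in str(source):
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(path)
        text = path.read_text()
        source_id = path.stem.upper()
    else:
        text = str(source)

    if format == "pdb":
        _validate_pdb_text(text)
        st = gemmi.read_pdb_string(text)
    else:
        doc = gemmi.cif.read_string(text)
        st = gemmi.make_structure_from_block(doc.sole_block())
    if not source_id:
        # raw text: trust an embedded id (HEADER / data block) if plausible
        name = (st.name or "").strip().upper()
        source_id = name if name and name != "STRING" else "STRUCTURE"

    if len(st) == 0:
        raise ValueError(f"{source_id}: empty structure (no models)")
    model = st[0]

    chains: dict[str, list[Residue]] = {}
    serial = 0
    n_atoms = 0
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            raw: list[AtomRecord] = []
            for atom in res:
                serial += 1
                raw.append(
                    AtomRecord(
                        serial=atom.serial or serial,
                        atom_name=atom.name,
                        element=atom.element.name,
                        res_name=res.name,
                        res_seq=res.seqid.num,
                        chain_id=chain.name,
                        coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                        altloc="" if atom.altloc in ("", "\x00") else atom.altloc,
                        occupancy=atom.occ,
                    )
                )
            atoms = _resolve_altlocs(raw)
            n_atoms += len(atoms)
            residues.append(
                Residue(
                    res_name=res.name,
                    res_seq=res.seqid.num,
                    chain_id=chain.name,
                    is_hetero=res.het_flag == "H",
                    atoms=atoms,
                )
            )
        if residues:
            chains.setdefault(chain.name, []).extend(residues)
    if n_atoms == 0:
        raise ValueError(f"{source_id}: empty model (no atoms)")
    return StructureModel(source_id=source_id, chains=chains)


# ---------------------------------------------------------------------------
# selections


def select_calpha(model: StructureModel, chain: str) -> MoleculeSelection:
    """One CA atom per standard residue of *chain*, ordered by residue number."""
    residues = [r for r in model.chain(chain) if r.is_standard]
    residues.sort(key=lambda r: r.res_seq)
    atoms: list[AtomRecord] = []
    for res in residues:
        ca = next((a for a in res.atoms if a.atom_name == "CA"), None)
        if ca is None:
            log.warning(
                "%s chain %s: residue %s %d has no CA atom; skipped",
                model.source_id, chain, res.res_name, res.res_seq,
            )
            continue
        atoms.append(ca)
    if not atoms:
        raise ValueError(f"{model.source_id} chain {chain}: no CA atoms")
    span = f"{atoms[0].res_seq}-{atoms[-1].res_seq}"
    return MoleculeSelection(
        atoms=atoms,
        provenance=Provenance(model.source_id, chain, span),
        mode="CA",
    )


def select_cofactor(model: StructureModel, annotation: CofactorAnnotation) -> MoleculeSelection:
    """All heavy atoms of the ligand named by an annotation row."""
    res = model.find_residue(annotation.chain, annotation.res_seq)
    if res is None or res.res_name != annotation.res_name:
        found = "absent" if res is None else f"found {res.res_name}"
        raise ValueError(
            f"annotation {annotation.pdb_id}/{annotation.role}: ligand "
            f"{annotation.res_name} {annotation.res_seq} on chain "
            f"{annotation.chain} — {found}"
        )
    atoms = res.heavy_atoms()
    if not atoms:
        raise ValueError(f"annotation {annotation.pdb_id}/{annotation.role}: no heavy atoms")
    return MoleculeSelection(
        atoms=atoms,
        provenance=Provenance(
            model.source_id,
            annotation.chain,
            f"{annotation.res_name}{annotation.res_seq}",
            role=annotation.role,
        ),
        mode="COFACTOR",
    )


def select_residue(model: StructureModel, chain: str, res_seq: int) -> MoleculeSelection:
    """All heavy atoms of one standard amino acid."""
    res = model.find_residue(chain, res_seq)
    if res is None:
        raise ValueError(f"{model.source_id} chain {chain}: residue {res_seq} absent")
    if not res.is_standard:
        raise ValueError(
            f"{model.source_id} chain {chain}: residue {res_seq} is {res.res_name}, "
            "not a standard amino acid; use select_cofactor for ligands"
        )
    return MoleculeSelection(
        atoms=res.heavy_atoms(),
        provenance=Provenance(model.source_id, chain, f"{res.res_name}{res_seq}"),
        mode="AA",
    )


def filter_atoms(selection: MoleculeSelection, excluded_names) -> MoleculeSelection:
    """Drop atoms whose name is in *excluded_names*; order otherwise preserved.

    The packaged phytol-tail preset (:data:`tsrkit.config.PHYTOL_TAIL`,
    C6–C20) removes the chlorophyll tail so that only the chlorin ring
    contributes triangles.
    """
    excluded = frozenset(excluded_names)
    atoms = [a for a in selection.atoms if a.atom_name not in excluded]
    if not atoms:
        raise ValueError("atom filter removed every atom of the selection")
    return MoleculeSelection(atoms=atoms, provenance=selection.provenance, mode=selection.mode)


def selection_to_pdb(selection: MoleculeSelection) -> str:
    """Render a selection as minimal PDB ATOM/HETATM records (for debugging)."""
    lines = []
    record = "ATOM  " if selection.mode == "CA" else "HETATM"
    for i, a in enumerate(selection.atoms, start=1):
        name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
        lines.append(
            f"{record}{i:5d} {name:<4.4s}{a.altloc or ' ':1s}{a.res_name:<3.3s} "
            f"{a.chain_id:1s}{a.res_seq:4d}    "
            f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
            f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2.2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# packaged annotations

_COFACTOR_ROLES = (
    "P700_A", "P700_B", "A_-1A", "A_-1B", "A_0A", "A_0B",
    "A_CA", "A_CB", "A_1A", "A_1B",
)


def load_cofactor_annotations(path: str | Path | None = None) -> list[CofactorAnnotation]:
    """Load the cofactor annotation table (the packaged PS I table by default).

    Columns (tab-delimited, ``#`` comments): pdb_id, role, chain, res_seq,
    res_name, axial_chain, axial_res.
    """
    if path is None:
        text = (
            resources.files("tsrkit").joinpath("data/cofactor_annotations.tsv").read_text()
        )
    else:
        text = Path(path).read_text()
    rows: list[CofactorAnnotation] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "pdb_id":  # header
            continue
        if len(parts) < 5:
            raise ValueError(f"annotation table line {lineno}: expected >= 5 columns")
        role = parts[1]
        if role not in _COFACTOR_ROLES:
            raise ValueError(f"annotation table line {lineno}: unknown role {role!r}")
        rows.append(
            CofactorAnnotation(
                pdb_id=parts[0],
                role=role,
                chain=parts[2],
                res_seq=int(parts[3]),
                res_name=parts[4],
                axial_chain=parts[5] if len(parts) > 5 else "",
                axial_res=parts[6] if len(parts) > 6 else "",
            )
        )
    return rows
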