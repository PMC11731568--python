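"""Deterministic synthetic structures for tests and examples.

The generators emit small, valid PDB text so every pipeline stage can run
with no download: an ideal-helix C-alpha trace standing in for a protein
chain, and a planar 25-heavy-atom macrocycle with chlorophyll-style atom
names (MG, NA–ND, ring carbons) plus an optional C6–C20 tail that extends
past 20 A to exercise the phytol-tail filter, MaxDist bin overflow and the
size-gap cutoff.  ``jitter_family`` turns one template into a family of
Gaussian-perturbed copies for clustering-recovery experiments.  None of this
mimics real chlorophyll chemistry — only the naming and rough topology the
selection filters care about.

All output is seed-deterministic.  ``fetch_structure`` (network, off the
testing path) downloads and caches an entry by PDB accession.
"""

from __future__ import annotations

import hashlib
import logging
import math
import urllib.error
import urllib.request
from pathlib import Path

import numpy as np

from .structure_io import MoleculeSelection

log = logging.getLogger(__name__)

__all__ = [
    "make_toy_protein",
    "make_toy_cofactor",
    "jitter_family",
    "fetch_structure",
]

_DEFAULT_PATTERN = ("GLY", "ALA", "TRP")


def _pdb_atom_line(serial, name, res_name, chain, res_seq, xyz, element, hetatm=False):
    record = "HETATM" if hetatm else "ATOM  "
    padded = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"{record}{serial:5d} {padded:<4.4s} {res_name:<3.3s} {chain:1s}{res_seq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          {element:>2.2s}"
    )


def make_toy_protein(
    n_residues: int,
    seed: int = 0,
    *,
    rise: float = 1.5,
    turn: float = 100.0,
    radius: float = 2.3,
    pattern: tuple[str, ...] = _DEFAULT_PATTERN,
    sigma: float = 0.0,
) -> str:
    """PDB text for an ideal-helix C-alpha trace.

    One CA per residue on a helix (default rise 1.5 A, 100 degree turn,
    radius 2.3 A), residue names cycling through *pattern*.  ``sigma`` adds
    seed-deterministic Gaussian jitter (default none).
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    rng = np.random.default_rng(seed)
    lines = []
    for i in range(n_residues):
        angle = math.radians(turn * i)
        xyz = np.array(
            [radius * math.cos(angle), radius * math.sin(angle), rise * i]
        )
        if sigma > 0:
            xyz = xyz + rng.normal(0.0, sigma, size=3)
        lines.append(
            _pdb_atom_line(
                i + 1, "CA", pattern[i % len(pattern)], "A", i + 1, xyz, "C"
            )
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_toy_cofactor(with_tail: bool = False, seed: int = 0, *, sigma: float = 0.0) -> str:
    """PDB text for a 25-heavy-atom macrocycle, optionally with a C6–C20 tail.

    Atom names follow chlorophyll conventions: central MG, four pyrrole
    nitrogens NA–ND, sixteen ring carbons C1A…C4D and four meso carbons
    C1–C4.  The optional tail adds fifteen carbons C6…C20 zig-zagging out to
    beyond 20 A from MG.  Radii and angles carry small irregular offsets so
    that no three atoms are exactly collinear.
    """
    rng = np.random.default_rng(seed)
    atoms: list[tuple[str, np.ndarray]] = [("MG", np.array([0.0, 0.0, 0.0]))]
    for i, name in enumerate(("NA", "NB", "NC", "ND")):
        ang = math.radians(45.0 + 90.0 * i + 1.7 * i)
        r = 2.00 + 0.045 * i
        atoms.append((name, np.array([r * math.cos(ang), r * math.sin(ang), 0.013 * i])))
    ring_names = [f"C{k}{ring}" for ring in "ABCD" for k in (1, 2, 3, 4)]
    for k, name in enumerate(ring_names):
        ang = math.radians(11.25 + 22.5 * k + 0.9 * math.sin(k))
        r = 3.25 + 0.017 * k
        atoms.append((name, np.array([r * math.cos(ang), r * math.sin(ang), 0.011 * k])))
    for k, name in enumerate(("C1", "C2", "C3", "C4")):
        ang = math.radians(10.0 + 90.0 * k + 2.3 * k)
        r = 3.62 + 0.023 * k
        atoms.append((name, np.array([r * math.cos(ang), r * math.sin(ang), -0.017 * k])))
    assert len(atoms) == 25
    if with_tail:
        for k in range(15):  # C6 … C20
            # quadratic y/z terms keep every atom triple off a common line
            xyz = np.array(
                [
                    5.0 + 1.45 * k,
                    0.45 * (-1) ** k + 0.03 * k + 0.011 * k * k,
                    0.55 + 0.071 * k - 0.0063 * k * k,
                ]
            )
            atoms.append((f"C{6 + k}", xyz))
    lines = []
    for serial, (name, xyz) in enumerate(atoms, start=1):
        if sigma > 0:
            xyz = xyz + rng.normal(0.0, sigma, size=3)
        element = "MG" if name == "MG" else name[0]
        lines.append(_pdb_atom_line(serial, name, "CLA", "A", 901, xyz, element, hetatm=True))
    lines.append("END")
    return "\n".join(lines) + "\n"


def jitter_family(
    template: MoleculeSelection,
    n_copies: int,
    sigma: float,
    seed: int,
) -> list[MoleculeSelection]:
    """Independent Gaussian-perturbed copies of a template selection.

    Each coordinate of each copy receives independent N(0, sigma^2) noise
    from one seeded generator; copy *i* is role-tagged ``<role>_j<i>``.
    """
    if n_copies < 1:
        raise ValueError("need at least one copy")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    base = template.coords
    base_role = template.provenance.label
    out = []
    for i in range(n_copies):
        noise = rng.normal(0.0, sigma, size=base.shape) if sigma > 0 else 0.0
        out.append(template.with_coords(base + noise, role=f"{base_role}_j{i}"))
    return out


def fetch_structure(
    accession: str,
    cache_dir: str | Path | None = None,
    timeout: float = 20.0,
) -> Path:
    """Download (or reuse a cached copy of) a PDB entry by 4-character accession.

    Network access is required on a cache miss; failures raise immediately
    with the underlying error — there is no retry.  The SHA-256 of each
    downloaded file is logged.
    """
    accession = accession.strip().upper()
    if len(accession) != 4 or not accession.isalnum():
        raise ValueError(f"not a PDB accession: {accession!r}")
    cache = Path(cache_dir) if cache_dir else Path.home() / ".cache" / "tsrkit"
    cache.mkdir(parents=True, exist_ok=True)
    target = cache / f"{accession}.pdb"
    if target.exists():
        log.info("cache hit for %s at %s", accession, target)
        return target
    url = f"https://files.rcsb.org/download/{accession}.pdb"
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            data = resp.read()
    except (urllib.error.URLError, OSError) as exc:
        raise RuntimeError(
            f"could not fetch {accession} from {url}: {exc}"
        ) from exc
    target.write_bytes(data)
    log.info(
        "fetched %s (%d bytes, sha256 %s)",
        accession, len(data), hashlib.sha256(data).hexdigest(),
    )
    return target
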