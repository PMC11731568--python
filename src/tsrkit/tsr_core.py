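"""TSR key generation: triangles -> ordered labels -> bins -> integer keys.

A molecule is represented by the multiset of integer keys over all C(n, 3)
triangles of its selected atoms.  For each triangle:

1. the three vertices are ordered by a deterministic rule — descending integer
   label, ties broken by descending distance to the triangle centroid, residual
   ties by ascending input index — giving labels (l1, l2, l3);
2. MaxDist (the longest edge, in A) and Theta (the acute angle at the midpoint
   of the l1–l2 edge between the median to l3 and the half-edge, in degrees)
   are computed and binned;
3. the tuple (l1, l2, l3, theta_bin, dist_bin) is packed into one integer by a
   mixed-radix code.

Because the ordering rule depends only on labels and internal geometry, the
key multiset is invariant under rigid motion and under permutation of the
input atom order.  Degenerate triangles (coincident or collinear vertices)
are skipped with a logged warning.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import BinningConfig
from .structure_io import AtomRecord, MoleculeSelection, Provenance

log = logging.getLogger(__name__)

__all__ = [
    "TriangleRecord",
    "KeyVector",
    "label_vertices",
    "triangle_geometry",
    "encode_key",
    "decode_key",
    "generate_keys",
    "write_key_file",
    "read_key_file",
    "write_triplet_file",
    "read_triplet_file",
    "TripletStore",
    "map_key_to_triangles",
]

_DEGENERATE_EPS = 1e-6
_THETA_EPS = 1e-9


@dataclass(frozen=True)
class TriangleRecord:
    """One triangle in (l1, l2, l3) vertex order."""

    vertex_ids: tuple[str, str, str]
    labels: tuple[int, int, int]
    maxdist: float
    theta: float
    theta_bin: int
    dist_bin: int
    key: int
    provenance: str = ""


@dataclass
class KeyVector:
    """Key -> occurrence frequency for one molecule (the "key file" content)."""

    provenance: Provenance
    mode: str
    config_hash: str
    counts: dict[int, int] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return self.provenance.label

    def distinct(self) -> int:
        return len(self.counts)

    def total(self) -> int:
        return sum(self.counts.values())

    def support(self) -> frozenset[int]:
        return frozenset(self.counts)


# ---------------------------------------------------------------------------
# single-triangle reference operations


def label_vertices(points):
    """Order three labeled points into (l1, l2, l3).

    *points* is a sequence of ``(label, xyz)`` pairs.  Returns
    ``(ordered_labels, order)`` where *order* indexes the input.  Sort rule:
    descending label; ties among equal labels by descending distance to the
    triangle centroid; residual ties by ascending input index.
    """
    if len(points) != 3:
        raise ValueError("exactly three points required")
    coords = np.array([np.asarray(p[1], dtype=float) for p in points])
    labels = [int(p[0]) for p in points]
    centroid = coords.mean(axis=0)
    cdist = np.linalg.norm(coords - centroid, axis=1)
    order = sorted(range(3), key=lambda i: (-labels[i], -cdist[i], i))
    return tuple(labels[i] for i in order), tuple(order)


def triangle_geometry(ordered_points):
    """(MaxDist, Theta) for three points already in (l1, l2, l3) order.

    Theta is measured at the midpoint M of the l1–l2 edge, between M->l3 and
    M->l2, folded to (0, 90] (an obtuse angle is replaced by its supplement;
    exactly 90 degrees is retained).  Raises ``ValueError`` for degenerate
    triangles (coincident points or zero-length median).
    """
    p = np.array([np.asarray(q, dtype=float) for q in ordered_points])
    d = (
        np.linalg.norm(p[0] - p[1]),
        np.linalg.norm(p[0] - p[2]),
        np.linalg.norm(p[1] - p[2]),
    )
    if min(d) < _DEGENERATE_EPS:
        raise ValueError("degenerate triangle: coincident points")
    mid = (p[0] + p[1]) / 2.0
    v1 = p[2] - mid
    v2 = p[1] - mid
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < _DEGENERATE_EPS or n2 < _DEGENERATE_EPS:
        raise ValueError("degenerate triangle: zero-length median or half-edge")
    cos = float(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))
    theta = float(np.degrees(np.arccos(cos)))
    if theta > 90.0:
        theta = 180.0 - theta
    if theta < _THETA_EPS:
        raise ValueError("degenerate triangle: collinear points")
    return float(max(d)), theta


# ---------------------------------------------------------------------------
# key encoding


def encode_key(l1: int, l2: int, l3: int, theta_bin: int, dist_bin: int, config: BinningConfig) -> int:
    """Mixed-radix pack of (l1, l2, l3, theta_bin, dist_bin) into one integer.

    ``key = ((l1-1) m^2 + (l2-1) m + (l3-1)) n_theta n_dist
    + (theta_bin-1) n_dist + (dist_bin-1)``; injective over the valid tuple
    space and inverted exactly by :func:`decode_key`.
    """
    m, nt, nd = config.m, config.n_theta, config.n_dist
    for value, upper, what in (
        (l1, m, "l1"), (l2, m, "l2"), (l3, m, "l3"),
        (theta_bin, nt, "theta_bin"), (dist_bin, nd, "dist_bin"),
    ):
        if not 1 <= value <= upper:
            raise ValueError(f"{what}={value} out of range [1, {upper}]")
    return ((l1 - 1) * m * m + (l2 - 1) * m + (l3 - 1)) * (nt * nd) + (
        theta_bin - 1
    ) * nd + (dist_bin - 1)


def decode_key(key: int, config: BinningConfig):
    """Invert :func:`encode_key`: key -> (l1, l2, l3, theta_bin, dist_bin)."""
    m, nt, nd = config.m, config.n_theta, config.n_dist
    if not 0 <= key < m * m * m * nt * nd:
        raise ValueError(f"key {key} out of range for this config")
    geom, labels = key % (nt * nd), key // (nt * nd)
    dist_bin = geom % nd + 1
    theta_bin = geom // nd + 1
    l3 = labels % m + 1
    labels //= m
    l2 = labels % m + 1
    l1 = labels // m + 1
    return l1, l2, l3, theta_bin, dist_bin


def _bin_index(values: np.ndarray, boundaries: tuple[float, ...]) -> np.ndarray:
    """1-based bin of each value against upper boundaries, clamped at both ends."""
    idx = np.searchsorted(np.asarray(boundaries), values, side="left") + 1
    return np.clip(idx, 1, len(boundaries))


# ---------------------------------------------------------------------------
# bulk generation


def _atom_id(atom: AtomRecord, mode: str) -> str:
    if mode == "CA":
        return f"{atom.chain_id}/{atom.res_name}{atom.res_seq}"
    return f"{atom.chain_id}/{atom.res_name}{atom.res_seq}/{atom.atom_name}"


def _atom_labels(selection: MoleculeSelection, config: BinningConfig) -> tuple[np.ndarray, list[int]]:
    """Integer label per atom; atoms without a label are reported for skipping."""
    labels = np.zeros(len(selection), dtype=np.int64)
    skipped: list[int] = []
    for i, atom in enumerate(selection.atoms):
        name = atom.res_name if config.mode == "CA" else (atom.element or "").upper()
        if not name and config.mode != "CA":
            # fall back to the leading letters of the atom name
            name = atom.atom_name.rstrip("0123456789ABD")[:2].upper()
        try:
            labels[i] = config.effective_label(name)
        except KeyError:
            skipped.append(i)
    return labels, skipped


def generate_keys(
    selection: MoleculeSelection,
    config: BinningConfig,
    records: bool = True,
    chunk_size: int = 500_000,
):
    """Enumerate all C(n, 3) triangles of a selection and encode their keys.

    Returns ``(KeyVector, list[TriangleRecord])``; the record list is empty
    when ``records=False`` (useful for large selections).  Triangles whose
    MaxDist exceeds ``config.size_gap_cutoff`` (if set) are dropped;
    degenerate triangles are skipped with a logged warning.
    """
    if selection.mode != config.mode:
        raise ValueError(
            f"selection mode {selection.mode} does not match config mode {config.mode}"
        )
    n = len(selection)
    if n < 3:
        raise ValueError(f"need at least 3 atoms to form a triangle, got {n}")

    labels, unlabeled = _atom_labels(selection, config)
    if unlabeled:
        names = {selection.atoms[i].res_name if config.mode == "CA" else selection.atoms[i].element
                 for i in unlabeled}
        log.warning(
            "%s: %d atoms with unmapped labels (%s) skipped",
            selection.provenance.label, len(unlabeled), sorted(names),
        )
        keep = np.ones(n, dtype=bool)
        keep[unlabeled] = False
        idx_keep = np.flatnonzero(keep)
        if idx_keep.size < 3:
            raise ValueError("fewer than 3 labeled atoms remain")
        atoms = [selection.atoms[i] for i in idx_keep]
        labels = labels[idx_keep]
    else:
        atoms = selection.atoms
    coords = np.array([a.coords for a in atoms], dtype=float)
    n = len(atoms)

    m, nt, nd = config.m, config.n_theta, config.n_dist
    theta_bounds = np.asarray(config.theta_bins)
    dist_bounds = np.asarray(config.dist_bins)
    ids = [_atom_id(a, config.mode) for a in atoms]
    prov_label = selection.provenance.label

    counts: dict[int, int] = {}
    out_records: list[TriangleRecord] = []
    n_degenerate = 0

    combo_iter = itertools.combinations(range(n), 3)
    while True:
        chunk = list(itertools.islice(combo_iter, chunk_size))
        if not chunk:
            break
        idx = np.asarray(chunk, dtype=np.int64)  # (T, 3)
        P = coords[idx]  # (T, 3, 3)
        d01 = np.linalg.norm(P[:, 0] - P[:, 1], axis=1)
        d02 = np.linalg.norm(P[:, 0] - P[:, 2], axis=1)
        d12 = np.linalg.norm(P[:, 1] - P[:, 2], axis=1)
        maxdist = np.maximum(np.maximum(d01, d02), d12)
        degenerate = np.minimum(np.minimum(d01, d02), d12) < _DEGENERATE_EPS

        L = labels[idx]  # (T, 3)
        centroid = P.mean(axis=1)
        cdist = np.linalg.norm(P - centroid[:, None, :], axis=2)
        pos = np.broadcast_to(np.arange(3), L.shape)
        order = np.lexsort((pos, -cdist, -L), axis=-1)  # (T, 3)
        Po = np.take_along_axis(P, order[..., None], axis=1)
        Lo = np.take_along_axis(L, order, axis=1)

        mid = (Po[:, 0] + Po[:, 1]) / 2.0
        v1 = Po[:, 2] - mid
        v2 = Po[:, 1] - mid
        n1 = np.linalg.norm(v1, axis=1)
        n2 = np.linalg.norm(v2, axis=1)
        degenerate |= (n1 < _DEGENERATE_EPS) | (n2 < _DEGENERATE_EPS)
        safe = np.where(degenerate, 1.0, n1 * n2)
        cos = np.clip(np.einsum("ij,ij->i", v1, v2) / safe, -1.0, 1.0)
        theta = np.degrees(np.arccos(cos))
        theta = np.where(theta > 90.0, 180.0 - theta, theta)
        degenerate |= theta < _THETA_EPS

        keep = ~degenerate
        n_degenerate += int(degenerate.sum())
        if config.size_gap_cutoff is not None:
            keep &= maxdist <= config.size_gap_cutoff
        if not keep.any():
            continue

        theta_bin = _bin_index(theta[keep], config.theta_bins)
        dist_bin = _bin_index(maxdist[keep], config.dist_bins)
        Lk = Lo[keep]
        keys = ((Lk[:, 0] - 1) * m * m + (Lk[:, 1] - 1) * m + (Lk[:, 2] - 1)) * (
            nt * nd
        ) + (theta_bin - 1) * nd + (dist_bin - 1)

        uniq, freq = np.unique(keys, return_counts=True)
        for k, f in zip(uniq.tolist(), freq.tolist()):
            counts[k] = counts.get(k, 0) + f

        if records:
            kept_idx = idx[keep]
            kept_order = order[keep]
            kept_max = maxdist[keep]
            kept_theta = theta[keep]
            for row in range(len(keys)):
                src = kept_idx[row][kept_order[row]]
                out_records.append(
                    TriangleRecord(
                        vertex_ids=tuple(ids[j] for j in src),
                        labels=tuple(int(x) for x in Lk[row]),
                        maxdist=float(kept_max[row]),
                        theta=float(kept_theta[row]),
                        theta_bin=int(theta_bin[row]),
                        dist_bin=int(dist_bin[row]),
                        key=int(keys[row]),
                        provenance=prov_label,
                    )
                )

    if n_degenerate:
        log.warning(
            "%s: skipped %d degenerate triangles", prov_label, n_degenerate
        )
    kv = KeyVector(
        provenance=selection.provenance,
        mode=config.mode,
        config_hash=config.config_hash(),
        counts=counts,
    )
    return kv, out_records


# ---------------------------------------------------------------------------
# key / triplet files


def _header_lines(mode: str, config_hash: str, provenance: Provenance,
                  config: BinningConfig | None) -> list[str]:
    lines = [
        "# tsrkit v1",
        f"# mode\t{mode}",
        f"# config\t{config_hash}",
        f"# provenance\t{provenance.source_id}\t{provenance.chain}\t"
        f"{provenance.span}\t{provenance.role}",
    ]
    if config is not None:
        lines.append("# theta_bins\t" + ",".join(repr(b) for b in config.theta_bins))
        lines.append("# dist_bins\t" + ",".join(repr(b) for b in config.dist_bins))
        lines.append(
            "# label_map\t"
            + ",".join(f"{k}:{v}" for k, v in sorted(config.label_map.items()))
        )
    return lines


def _parse_header(lines: list[str]):
    meta: dict[str, str] = {}
    prov = Provenance("", "", "")
    for line in lines:
        if not line.startswith("# "):
            continue
        parts = line[2:].split("\t")
        if parts[0] == "provenance":
            parts += [""] * (5 - len(parts))
            prov = Provenance(parts[1], parts[2], parts[3], parts[4])
        elif len(parts) >= 2:
            meta[parts[0]] = parts[1]
    return meta, prov


def write_key_file(kv: KeyVector, path: str | Path, config: BinningConfig | None = None) -> None:
    """Write a key file: header block plus tab-delimited (key, frequency) rows."""
    if not kv.counts:
        raise ValueError("refusing to write an empty KeyVector")
    lines = _header_lines(kv.mode, kv.config_hash, kv.provenance, config)
    lines.append("key\tfrequency")
    for key in sorted(kv.counts):
        lines.append(f"{key}\t{kv.counts[key]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_key_file(path: str | Path) -> KeyVector:
    lines = Path(path).read_text().splitlines()
    header = [l for l in lines if l.startswith("#")]
    meta, prov = _parse_header(header)
    counts: dict[int, int] = {}
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("#") or line.startswith("key\t") or not line.strip():
            continue
        parts = line.split("\t")
        try:
            key, freq = int(parts[0]), int(parts[1])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}: malformed key-file row at line {lineno}") from exc
        counts[key] = freq
    return KeyVector(
        provenance=prov,
        mode=meta.get("mode", ""),
        config_hash=meta.get("config", ""),
        counts=counts,
    )


_TRIPLET_COLUMNS = (
    "v1_id\tl1\tv2_id\tl2\tv3_id\tl3\tmaxdist\ttheta\ttheta_bin\tdist_bin\tkey"
)


def write_triplet_file(
    records: list[TriangleRecord],
    kv: KeyVector,
    path: str | Path,
    config: BinningConfig | None = None,
) -> None:
    """Write a triplet file: one row per triangle with vertex details and key."""
    if not records:
        raise ValueError("refusing to write an empty triplet file")
    lines = _header_lines(kv.mode, kv.config_hash, kv.provenance, config)
    lines.append(_TRIPLET_COLUMNS)
    for r in records:
        lines.append(
            f"{r.vertex_ids[0]}\t{r.labels[0]}\t{r.vertex_ids[1]}\t{r.labels[1]}\t"
            f"{r.vertex_ids[2]}\t{r.labels[2]}\t{r.maxdist!r}\t{r.theta!r}\t"
            f"{r.theta_bin}\t{r.dist_bin}\t{r.key}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_triplet_file(path: str | Path):
    """Read a triplet file back into ``(provenance, list[TriangleRecord])``."""
    lines = Path(path).read_text().splitlines()
    meta, prov = _parse_header([l for l in lines if l.startswith("#")])
    records: list[TriangleRecord] = []
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("#") or line.startswith("v1_id") or not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 11:
            raise ValueError(f"{path}: malformed triplet row at line {lineno}")
        try:
            records.append(
                TriangleRecord(
                    vertex_ids=(parts[0], parts[2], parts[4]),
                    labels=(int(parts[1]), int(parts[3]), int(parts[5])),
                    maxdist=float(parts[6]),
                    theta=float(parts[7]),
                    theta_bin=int(parts[8]),
                    dist_bin=int(parts[9]),
                    key=int(parts[10]),
                    provenance=prov.label,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: malformed triplet row at line {lineno}") from exc
    return prov, records


class TripletStore:
    """In-memory collection of triplet records across molecules, indexed by key."""

    def __init__(self) -> None:
        self._by_key: dict[int, list[TriangleRecord]] = {}

    def add_records(self, records: list[TriangleRecord]) -> None:
        for r in records:
            self._by_key.setdefault(r.key, []).append(r)

    def add_file(self, path: str | Path) -> None:
        _, records = read_triplet_file(path)
        self.add_records(records)

    def lookup(self, key: int) -> list[TriangleRecord]:
        return list(self._by_key.get(key, []))


def map_key_to_triangles(key: int, store: TripletStore) -> list[TriangleRecord]:
    """All triangles bearing *key* across the store (empty list if absent)."""
    return store.lookup(key)
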