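"""Set and multiset algebra over key vectors.

Similarity between two molecules is the Generalized Jaccard coefficient of
their key-frequency vectors, sum_k min(f_a, f_b) / sum_k max(f_a, f_b); the
frequency-free variant (set Jaccard over key supports) is the Normalized
Jaccard used for single amino acids.  Key taxonomy follows the field's usage:

* distinct / total keys of one molecule: |support| / sum of frequencies;
* common keys of a group: keys present in every member;
* specific keys of a group against contrast groups: keys present in every
  member of the group and absent from every member of every contrast group;
* Venn regions: exclusive/shared key counts between group-level key unions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .tsr_core import KeyVector

__all__ = [
    "KeyGroup",
    "SimilarityMatrix",
    "generalized_jaccard",
    "normalized_jaccard",
    "count_keys",
    "common_keys",
    "specific_keys",
    "venn_regions",
    "similarity_matrix",
    "to_distance",
]


def _check_comparable(a: KeyVector, b: KeyVector) -> None:
    if a.mode != b.mode or a.config_hash != b.config_hash:
        raise ValueError(
            "key vectors are not comparable: "
            f"({a.mode}, {a.config_hash}) vs ({b.mode}, {b.config_hash})"
        )


def generalized_jaccard(a: KeyVector, b: KeyVector) -> float:
    """Frequency-aware Jaccard similarity: sum min / sum max over frequencies."""
    _check_comparable(a, b)
    num = 0
    den = 0
    for key in a.support() | b.support():
        fa = a.counts.get(key, 0)
        fb = b.counts.get(key, 0)
        num += min(fa, fb)
        den += max(fa, fb)
    return num / den if den else 0.0


def normalized_jaccard(a: KeyVector, b: KeyVector) -> float:
    """Frequency-free set Jaccard over key supports."""
    _check_comparable(a, b)
    sa, sb = a.support(), b.support()
    union = len(sa | sb)
    return len(sa & sb) / union if union else 0.0


def count_keys(kv: KeyVector) -> tuple[int, int]:
    """(distinct, total) key counts of one molecule."""
    if not kv.counts:
        raise ValueError("empty key vector")
    return kv.distinct(), kv.total()


@dataclass
class KeyGroup:
    """A named set of key vectors (e.g. all P700 pigments)."""

    name: str
    members: list[KeyVector]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group {self.name!r} has no members")
        ref = self.members[0]
        for kv in self.members[1:]:
            _check_comparable(ref, kv)

    def union_support(self) -> frozenset[int]:
        out: frozenset[int] = frozenset()
        for kv in self.members:
            out |= kv.support()
        return out

    def intersection_support(self) -> frozenset[int]:
        out = self.members[0].support()
        for kv in self.members[1:]:
            out &= kv.support()
        return out


def _spread(values) -> dict[str, float]:
    arr = np.asarray(list(values), dtype=float)
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "p25": float(np.percentile(arr, 25)),
        "p75": float(np.percentile(arr, 75)),
    }


def common_keys(group: KeyGroup) -> dict:
    """Keys present in every member of a group, with per-member totals.

    Returns distinct common keys (the intersection of supports), each member's
    total common count (sum of its own frequencies over those keys), and group
    aggregates (mean, SD, 25/75 percentiles) of both distinct and total
    common counts.
    """
    distinct_common = group.intersection_support()
    per_member_total = {
        kv.label: sum(kv.counts[k] for k in distinct_common) for kv in group.members
    }
    return {
        "group": group.name,
        "distinct_common": sorted(distinct_common),
        "n_distinct_common": len(distinct_common),
        "per_member_total_common": per_member_total,
        "total_common_stats": _spread(per_member_total.values()),
        "distinct_stats": _spread(kv.distinct() for kv in group.members),
        "total_stats": _spread(kv.total() for kv in group.members),
    }


def specific_keys(target: KeyGroup, others: list[KeyGroup]) -> frozenset[int]:
    """Keys present in every member of *target*, absent from every member of *others*."""
    keys = target.intersection_support()
    for group in others:
        for kv in group.members:
            keys -= kv.support()
    return keys


def venn_regions(groups: list[KeyGroup], level: str = "group-union") -> dict[str, int]:
    """Key counts for each of the 2^g - 1 Venn regions of g groups.

    ``group-union`` pools each group's member supports into one set before
    computing regions; ``all-members`` intersects member supports instead
    (a key must occur in every member to count for its group).
    """
    if level not in ("group-union", "all-members"):
        raise ValueError(f"unknown level {level!r}")
    supports = {
        g.name: (g.union_support() if level == "group-union" else g.intersection_support())
        for g in groups
    }
    names = [g.name for g in groups]
    regions: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for inside in combinations(names, r):
            keys = supports[inside[0]]
            for name in inside[1:]:
                keys = keys & supports[name]
            for name in names:
                if name not in inside:
                    keys = keys - supports[name]
            regions["&".join(inside)] = len(keys)
    return regions


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity matrix with labels and measure metadata."""

    labels: list[str]
    values: np.ndarray
    measure: str
    config_hash: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity matrix must be symmetric")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, measure: str = "external") -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(labels=list(df.index), values=df.to_numpy(), measure=measure)


_MEASURES = {
    "generalized_jaccard": generalized_jaccard,
    "normalized_jaccard": normalized_jaccard,
}


def similarity_matrix(members: list[KeyVector], measure: str = "generalized_jaccard") -> SimilarityMatrix:
    """All-pairs similarity of a list of key vectors (unit diagonal)."""
    try:
        fn = _MEASURES[measure]
    except KeyError:
        raise ValueError(f"unknown measure {measure!r}") from None
    n = len(members)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = fn(members[i], members[j])
    return SimilarityMatrix(
        labels=[kv.label for kv in members],
        values=values,
        measure=measure,
        config_hash=members[0].config_hash if members else "",
    )


def to_distance(sim: SimilarityMatrix) -> np.ndarray:
    """Distance matrix 1 - S, elementwise (zero diagonal)."""
    d = 1.0 - sim.values
    np.fill_diagonal(d, 0.0)
    return d
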