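"""Average-linkage clustering, classical MDS, ARI, and the two-group test.

The clustering is plain UPGMA over a precomputed distance matrix (typically
1 - Generalized Jaccard).  Merge ties are resolved deterministically by the
smallest leaf-index pair so that repeated runs give byte-identical trees.
Dendrograms export to Newick with UPGMA heights; flat partitions at a
requested k are scored against ground-truth classes with the adjusted Rand
index (ARI; 1 = perfect recovery, ~0 = chance, can be negative).  Group
comparisons use Welch's unequal-variance t-test with the conventional
significance stars at p < 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "ClusterResult",
    "average_linkage",
    "cut_clusters",
    "classical_mds",
    "adjusted_rand_index",
    "two_group_test",
    "significance_stars",
]


def _check_distance_matrix(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if (dist < 0).any():
        raise ValueError("distance matrix must be non-negative")
    return dist


@dataclass
class ClusterResult:
    """UPGMA merge tree in scipy linkage format plus leaf labels."""

    linkage: np.ndarray  # (n-1, 4): child i, child j, height, size
    leaf_labels: list[str]
    matrix_hash: str

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def cut(self, k: int) -> np.ndarray:
        return cut_clusters(self, k)

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights.

        Children of every internal node are ordered smallest-leaf-index
        first, making the leaf order deterministic.
        """
        n = self.n_leaves
        heights = np.concatenate([np.zeros(n), self.linkage[:, 2]])
        min_leaf = list(range(n)) + [0] * (n - 1)
        for row in range(n - 1):
            i, j = int(self.linkage[row, 0]), int(self.linkage[row, 1])
            min_leaf[n + row] = min(min_leaf[i], min_leaf[j])

        def render(node: int, parent_height: float) -> str:
            length = parent_height - heights[node]
            if node < n:
                return f"{self.leaf_labels[node]}:{length:.6g}"
            row = node - n
            children = sorted(
                (int(self.linkage[row, 0]), int(self.linkage[row, 1])),
                key=lambda c: min_leaf[c],
            )
            inner = ",".join(render(c, heights[node]) for c in children)
            return f"({inner}):{length:.6g}"

        root = 2 * n - 2
        row = root - n
        children = sorted(
            (int(self.linkage[row, 0]), int(self.linkage[row, 1])),
            key=lambda c: min_leaf[c],
        )
        inner = ",".join(render(c, heights[root]) for c in children)
        return f"({inner});"


def average_linkage(dist: np.ndarray, leaf_labels: list[str] | None = None) -> ClusterResult:
    """UPGMA merge tree from a square distance matrix.

    At each step the pair of clusters with the smallest average inter-cluster
    distance is merged; ties are broken by the smallest leaf-index pair.  The
    inter-cluster distance to a merged cluster is the size-weighted average,
    so heights are the exact average distances over all cross pairs.
    """
    dist = _check_distance_matrix(dist)
    n = dist.shape[0]
    if n < 2:
        raise ValueError("need at least two observations")
    if leaf_labels is None:
        leaf_labels = [str(i) for i in range(n)]
    if len(leaf_labels) != n:
        raise ValueError("leaf label count does not match matrix size")

    # active clusters: id -> (size, min leaf index); distances in a dict
    size = {i: 1 for i in range(n)}
    min_leaf = {i: i for i in range(n)}
    d = {
        (i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    active = set(range(n))
    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for (i, j), dij in d.items():
            cand = (dij, min(min_leaf[i], min_leaf[j]), max(min_leaf[i], min_leaf[j]))
            if best is None or cand < best[0]:
                best = (cand, i, j)
        (_, _, _), i, j = best  # type: ignore[misc]
        dij = d.pop((i, j))
        Z[step] = (i, j, dij, size[i] + size[j])
        # size-weighted average distance from the merged cluster to the rest
        for k in sorted(active - {i, j}):
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            dnew = (size[i] * dik + size[j] * djk) / (size[i] + size[j])
            d[(k, next_id)] = dnew
        size[next_id] = size[i] + size[j]
        min_leaf[next_id] = min(min_leaf[i], min_leaf[j])
        active -= {i, j}
        active.add(next_id)
        next_id += 1

    matrix_hash = hashlib.sha1(np.ascontiguousarray(dist).tobytes()).hexdigest()[:12]
    return ClusterResult(linkage=Z, leaf_labels=list(leaf_labels), matrix_hash=matrix_hash)


def cut_clusters(result: ClusterResult, k: int) -> np.ndarray:
    """Flat k-cluster partition from the merge tree (labels 1..k)."""
    if not 1 <= k <= result.n_leaves:
        raise ValueError(f"k must be in [1, {result.n_leaves}]")
    return fcluster(result.linkage, t=k, criterion="maxclust")


def classical_mds(dist: np.ndarray, dim: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS embedding of a distance matrix.

    Double-centers the squared distances and takes the top *dim* spectral
    components.  Components with negative eigenvalues (non-Euclidean input)
    are truncated to zero with a warning.
    """
    dist = _check_distance_matrix(dist)
    n = dist.shape[0]
    if not 1 <= dim < n:
        raise ValueError(f"dim must be in [1, {n - 1}]")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dist ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1][:dim]
    lam = eigvals[order]
    if (eigvals < -1e-9 * max(1.0, abs(eigvals).max())).any():
        warnings.warn(
            "distance matrix is not Euclidean in the requested dimension; "
            "negative eigenvalues truncated",
            stacklevel=2,
        )
    lam = np.clip(lam, 0.0, None)
    return eigvecs[:, order] * np.sqrt(lam)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Permutation-model adjusted Rand index between two partitions."""
    labels_a = list(labels_a)
    labels_b = list(labels_b)
    if len(labels_a) != len(labels_b):
        raise ValueError("partitions must label the same items")
    return float(adjusted_rand_score(labels_a, labels_b))


def two_group_test(x, y) -> tuple[float, float]:
    """Welch two-sample t-test; returns (t statistic, two-sided p-value)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two observations")
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def significance_stars(p: float) -> str:
    """Conventional star annotation: *** p<0.001, ** p<0.01, * p<0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
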