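"""Hierarchical clustering with the uncentered-correlation similarity.

Implements the Cluster-3.0-style workflow: optional median centering and
median-absolute-deviation scaling of profile vectors, pairwise distances
1 - r where r is the uncentered correlation (cosine similarity), and
deterministic agglomerative clustering with a lexicographic tie-break on
cluster indices. Trees export to Newick for dendrogram viewers, with merge
heights split equally between the two children (the midpoint convention,
since agglomerative trees carry node heights, not branch lengths).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

LINKAGES = ("average", "complete", "single", "centroid")


@dataclass
class ClusterTree:
    """Binary dendrogram: leaves 0..n-1, internal nodes n..2n-2.

    merges[k] = (node_a, node_b, height) creates internal node n+k.
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise ValueError(f"{n} leaves require {n - 1} merges, got {len(self.merges)}")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def root(self) -> int:
        return 2 * self.n_leaves - 2

    def node_height(self, node: int) -> float:
        n = self.n_leaves
        return 0.0 if node < n else self.merges[node - n][2]

    def children(self, node: int) -> Optional[tuple[int, int]]:
        n = self.n_leaves
        if node < n:
            return None
        a, b, _ = self.merges[node - n]
        return a, b

    def leaf_sets(self) -> dict[int, frozenset[int]]:
        """Leaf-index set under each node (for tree comparison in tests)."""
        n = self.n_leaves
        sets: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
        for k, (a, b, _) in enumerate(self.merges):
            sets[n + k] = sets[a] | sets[b]
        return sets


# ---------------------------------------------------------------------------
# similarity / preprocessing

def uncentered_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Uncentered correlation (cosine similarity) between two vectors.

    r = sum(x_i * y_i) / (||x|| * ||y||), no mean subtraction. An all-zero
    vector gives r = 0 with a warning (documented convention).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("vectors must be 1-D and of equal nonzero length")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        warnings.warn("all-zero vector in uncentered correlation; r defined as 0")
        return 0.0
    return float(np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0))


def uncentered_correlation_distance_matrix(matrix: np.ndarray) -> np.ndarray:
    """Pairwise 1 - r over the rows of *matrix*."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = uncentered_correlation(matrix[i], matrix[j])
            d[i, j] = d[j, i] = 1.0 - r
    return d


def median_center(
    matrix: np.ndarray, axis: int = 1, scale: bool = True
) -> np.ndarray:
    """Median-center (and MAD-scale) vectors along *axis*.

    Each vector has its median subtracted; when ``scale`` is true it is then
    divided by its median absolute deviation, left unchanged where MAD = 0.
    axis=1 centers rows, axis=0 centers columns.
    """
    m = np.asarray(matrix, dtype=float).copy()
    med = np.median(m, axis=axis, keepdims=True)
    m = m - med
    if scale:
        mad = np.median(np.abs(m), axis=axis, keepdims=True)
        safe = np.where(mad > 0, mad, 1.0)
        m = m / safe
    return m


# ---------------------------------------------------------------------------
# agglomeration

def _lw_update(
    linkage: str,
    d_ai: float,
    d_bi: float,
    d_ab: float,
    na: int,
    nb: int,
) -> float:
    """Lance-Williams distance from merged cluster (a u b) to cluster i."""
    if linkage == "single":
        return min(d_ai, d_bi)
    if linkage == "complete":
        return max(d_ai, d_bi)
    if linkage == "average":
        return (na * d_ai + nb * d_bi) / (na + nb)
    if linkage == "centroid":
        nab = na + nb
        sq = (
            (na * d_ai**2 + nb * d_bi**2) / nab
            - (na * nb * d_ab**2) / (nab**2)
        )
        return float(np.sqrt(max(sq, 0.0)))
    raise ValueError(f"unknown linkage {linkage!r}")


def hcluster(
    matrix: Optional[np.ndarray] = None,
    labels: Optional[Sequence[str]] = None,
    linkage: str = "average",
    dist: Optional[np.ndarray] = None,
) -> ClusterTree:
    """Deterministic agglomerative clustering.

    Rows of *matrix* are clustered under the uncentered-correlation distance
    (or a precomputed symmetric distance matrix may be given as *dist*).
    At every step the pair at minimal distance merges; exact ties break on
    the lexicographically smallest pair of cluster indices, making the tree
    reproducible across platforms.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    if dist is None:
        if matrix is None:
            raise ValueError("provide a data matrix or a distance matrix")
        matrix = np.asarray(matrix, dtype=float)
        dist = uncentered_correlation_distance_matrix(matrix)
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows to cluster")
    if not np.all(np.isfinite(dist)):
        raise ValueError("non-finite distances")
    if labels is None:
        labels = [str(i) for i in range(n)]
    labels = tuple(str(x) for x in labels)
    if len(labels) != n:
        raise ValueError("label count does not match matrix rows")

    # active cluster id -> (current distance row key); distances kept in a dict
    d = {(i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)}
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    merges: list[tuple[int, int, float]] = []
    next_id = n

    def dd(i: int, j: int) -> float:
        return d[(i, j) if i < j else (j, i)]

    while len(active) > 1:
        best_pair, best_dist = None, np.inf
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                v = dd(i, j)
                if v < best_dist or (v == best_dist and best_pair is None):
                    best_pair, best_dist = (i, j), v
        a, b = best_pair
        d_ab = best_dist
        merges.append((a, b, d_ab))
        active.discard(a)
        active.discard(b)
        for i in sorted(active):
            d[(i, next_id)] = _lw_update(
                linkage, dd(a, i), dd(b, i), d_ab, size[a], size[b]
            )
        size[next_id] = size[a] + size[b]
        active.add(next_id)
        next_id += 1

    return ClusterTree(leaves=labels, merges=tuple(merges))


# ---------------------------------------------------------------------------
# profile-level entry points

def profile_matrix(profiles, catalog, columns: str = "all_copper"):
    """(species x type) count matrix plus row and column labels.

    ``columns``: 'all_copper' keeps all catalog types; 'homeostasis_only'
    keeps the types whose categories include homeostasis (dual-membership
    types included).
    """
    if columns == "all_copper":
        cols = list(catalog.type_names)
    elif columns == "homeostasis_only":
        cols = [t.type_name for t in catalog.types_in_category("homeostasis")]
    else:
        raise ValueError(f"unknown column subset {columns!r}")
    rows = [p.species_id for p in profiles]
    mat = np.array([[p.count(c) for c in cols] for p in profiles], dtype=float)
    return mat, rows, cols


def subset_cluster(
    profiles,
    catalog,
    columns: str = "all_copper",
    row_subset: Optional[Sequence[str]] = None,
    linkage: str = "average",
    center: bool = True,
) -> ClusterTree:
    """Cluster species by a column subset of their copper-type profiles.

    Columns are optionally median-centered and MAD-scaled (per type, i.e.
    along species) before the uncentered-correlation distance is taken.
    """
    if row_subset is not None:
        keep = set(row_subset)
        profiles = [p for p in profiles if p.species_id in keep]
    if not profiles:
        raise ValueError("empty species subset")
    mat, rows, _cols = profile_matrix(profiles, catalog, columns)
    if center:
        mat = median_center(mat, axis=0, scale=True)
    return hcluster(mat, labels=rows, linkage=linkage)


def cluster_types(profiles, catalog, linkage: str = "average") -> ClusterTree:
    """Co-occurrence clustering of the protein types (no centering):
    columns of the species-by-type matrix are the objects."""
    mat, _rows, cols = profile_matrix(profiles, catalog, "all_copper")
    return hcluster(mat.T, labels=cols, linkage=linkage)


# ---------------------------------------------------------------------------
# Newick export

def _escape_label(label: str) -> str:
    if any(c in label for c in " ()[]:;,'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: ClusterTree) -> str:
    """Newick text with branch lengths.

    Node elevations are half the merge heights (midpoint convention), so a
    two-leaf tree merged at height 0.4 renders as ``(A:0.2,B:0.2);``.
    """

    def elev(node: int) -> float:
        return tree.node_height(node) / 2.0

    def render(node: int) -> str:
        ch = tree.children(node)
        if ch is None:
            return _escape_label(tree.leaves[node])
        a, b = ch
        ba = elev(node) - elev(a)
        bb = elev(node) - elev(b)
        return f"({render(a)}:{ba:.10g},{render(b)}:{bb:.10g})"

    return render(tree.root) + ";"


def write_newick(tree: ClusterTree, path) -> None:
    from pathlib import Path

    Path(path).write_text(to_newick(tree) + "\n")
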