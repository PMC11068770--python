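"""SNP-based genetic-diversity clustering.

Pairwise identity-by-state (IBS) distances from dosage data,
complete-linkage agglomeration with a deterministic lexicographic tie-break,
ultrametric Newick export, and flat k-cluster cuts.

The distance between accessions i and j is the mean allele difference over
their pairwise non-missing SNPs, ``d = sum |g_i - g_j| / (2 m)``; identical
genotypes give 0 and opposite homozygotes across every SNP give 1.  The
agglomeration is the classic O(n^3) complete-linkage loop (inter-cluster
distance = maximum member distance), which guarantees monotone merge
heights; merge records follow the scipy linkage-matrix convention so the
result interoperates with scipy plotting utilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .errors import DataFormatError, ModelError
from .genotype import GenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "IBSCompleteLinkage",
    "ibs_distance",
    "complete_linkage",
    "to_newick",
    "cut_clusters",
]


@dataclass
class DistanceMatrix:
    """Symmetric accession distance matrix in [0, 1] with pair SNP counts."""

    values: np.ndarray
    labels: list[str]
    pair_counts: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise DataFormatError("distance shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise DataFormatError("distance matrix is not symmetric")
        if np.diag(self.values).any():
            raise DataFormatError("distance diagonal must be zero")
        if (self.values < -1e-12).any() or (self.values > 1 + 1e-12).any():
            raise DataFormatError("distances must lie in [0, 1]")


@dataclass
class Dendrogram:
    """Merge list in scipy linkage convention plus leaf labels.

    Row t of ``linkage`` is (node_a, node_b, height, size); leaves are
    0..n-1 and the cluster created at step t gets id n + t.
    """

    linkage: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.linkage = np.asarray(self.linkage, dtype=float)
        n = len(self.labels)
        if self.linkage.shape != (max(n - 1, 0), 4):
            raise DataFormatError("linkage must have n-1 rows of 4")
        heights = self.linkage[:, 2]
        if len(heights) and (np.diff(heights) < -1e-12).any():
            raise DataFormatError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)


def ibs_distance(G: GenotypeMatrix) -> DistanceMatrix:
    """Mean allele-sharing distance over pairwise non-missing SNPs."""
    if G.n_accessions < 2:
        raise ModelError("need at least two accessions")
    dos = G.dosage
    called = ~np.isnan(dos)
    n = G.n_accessions
    D = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    filled = np.where(called, dos, 0.0)
    for i in range(n):
        shared = called & called[i]
        m = shared.sum(axis=1)
        diff = np.where(shared, np.abs(filled - filled[i]), 0.0).sum(axis=1)
        counts[i] = m
        with np.errstate(invalid="ignore", divide="ignore"):
            D[i] = diff / (2.0 * m)
    for i in range(n):
        for j in range(i + 1, n):
            if counts[i, j] == 0:
                raise ModelError(
                    f"accessions {G.accession_ids[i]!r} and "
                    f"{G.accession_ids[j]!r} share no non-missing SNPs"
                )
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D, list(G.accession_ids), counts)


def complete_linkage(D: DistanceMatrix | np.ndarray,
                     labels: list[str] | None = None) -> Dendrogram:
    """Agglomerative clustering with maximum-linkage update.

    At each step the pair of active clusters at minimum distance merges;
    exact ties are broken by the lexicographically smallest (id_a, id_b)
    pair, making the result deterministic.
    """
    if isinstance(D, DistanceMatrix):
        labels = list(D.labels)
        dist = D.values.copy()
    else:
        dist = np.asarray(D, dtype=float).copy()
        if labels is None:
            labels = [str(i) for i in range(dist.shape[0])]
    n = dist.shape[0]
    # working distances between active nodes keyed by scipy-style node ids
    active: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            active[i][j] = dist[i, j]
            active[j][i] = dist[i, j]
    sizes = {i: 1 for i in range(n)}
    merges = []
    next_id = n
    for step in range(n - 1):
        best = None
        for a in sorted(active):
            for b in sorted(active[a]):
                if b <= a:
                    continue
                d = active[a][b]
                if best is None or d < best[0] or (d == best[0] and (a, b) < best[1:]):
                    best = (d, a, b)
        d, a, b = best
        new_nbrs = {}
        for c in active:
            if c in (a, b):
                continue
            new_nbrs[c] = max(active[a][c], active[b][c])
        del active[a], active[b]
        for c in active:
            active[c].pop(a, None)
            active[c].pop(b, None)
            active[c][next_id] = new_nbrs[c]
        active[next_id] = new_nbrs
        sizes[next_id] = sizes[a] + sizes[b]
        merges.append((a, b, d, sizes[next_id]))
        next_id += 1
    return Dendrogram(np.array(merges).reshape(max(n - 1, 0), 4), labels)


def _newick_label(label: str) -> str:
    if any(ch in label for ch in "(),:;'\" \t[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: Dendrogram) -> str:
    """Ultrametric Newick string.

    Branch lengths are half the height difference between parent and child
    merges, so the path between any two leaves through their common ancestor
    equals the cophenetic (merge) height and every leaf sits at depth
    root_height / 2.
    """
    n = tree.n_leaves
    heights = {i: 0.0 for i in range(n)}
    children = {}
    for t, (a, b, h, _size) in enumerate(tree.linkage):
        node = n + t
        children[node] = (int(a), int(b))
        heights[node] = float(h)

    def render(node: int, parent_height: float) -> str:
        length = (parent_height - heights[node]) / 2.0
        if node < n:
            return f"{_newick_label(tree.labels[node])}:{length:.10g}"
        a, b = children[node]
        h = heights[node]
        return f"({render(a, h)},{render(b, h)}):{length:.10g}"

    if n == 1:
        return f"{_newick_label(tree.labels[0])}:0;"
    root = n + len(tree.linkage) - 1
    a, b = children[root]
    h = heights[root]
    return f"({render(a, h)},{render(b, h)});"


def cut_clusters(tree: Dendrogram, k: int) -> dict[str, int]:
    """Partition into k flat clusters by stopping after n - k merges.

    Cluster ids (1-based) are assigned by the order of each cluster's first
    leaf in the input labelling.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ModelError(f"k must be in [1, {n}], got {k}")
    parent = list(range(n + len(tree.linkage)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n - k):
        a, b, _h, _s = tree.linkage[t]
        node = n + t
        parent[find(int(a))] = node
        parent[find(int(b))] = node
    roots: dict[int, int] = {}
    assignment = {}
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots) + 1
        assignment[tree.labels[leaf]] = roots[r]
    return assignment


class IBSCompleteLinkage(BaseEstimator):
    """Estimator wrapper: IBS distances + complete linkage + flat cut.

    Parameters
    ----------
    n_clusters:
        Number of flat clusters returned by :meth:`fit_predict`.
    """

    def __init__(self, n_clusters: int = 3):
        self.n_clusters = n_clusters

    def fit(self, G: GenotypeMatrix, y=None) -> "IBSCompleteLinkage":
        self.distance_ = ibs_distance(G)
        self.tree_ = complete_linkage(self.distance_)
        return self

    def fit_predict(self, G: GenotypeMatrix, y=None) -> np.ndarray:
        self.fit(G)
        assignment = cut_clusters(self.tree_, self.n_clusters)
        self.labels_ = np.array([assignment[a] for a in self.tree_.labels])
        return self.labels_
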