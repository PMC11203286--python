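"""Hierarchical clustering of bucket fingerprints.

Euclidean distances between fingerprint rows feed agglomerative
clustering under Ward's minimum-variance criterion, implemented with the
Lance-Williams update on squared distances (Ward.D2 semantics: merge
heights are reported back on the distance scale, so two singletons merge
at exactly their Euclidean distance).  Ties are broken toward the lowest
(i, j) cluster-index pair for bit-reproducibility.  The dendrogram can
be cut into flat clusters and scored for species recovery, and exported
as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .bucket import BucketTable

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "euclidean_distances",
    "ward_linkage",
    "cut_tree",
    "species_recovery",
    "to_newick",
]


@dataclass
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be exactly 0")
        if self.values.size and self.values.min() < 0:
            raise ValueError("distances must be non-negative")


@dataclass
class Dendrogram:
    """Agglomerative merge history.

    ``merges`` rows are (cluster_a, cluster_b, height, new_size) with
    scipy-style ids: leaves are 0..n-1, the cluster created by merge k is
    n + k.  Ward heights are monotone non-decreasing.
    """

    merges: tuple[tuple[int, int, float, int], ...]
    leaf_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.leaf_labels)
        if len(self.merges) != n - 1:
            raise ValueError(f"expected {n - 1} merges for {n} leaves, got {len(self.merges)}")
        heights = [m[2] for m in self.merges]
        for a, b in zip(heights, heights[1:]):
            if b < a - 1e-9 * max(1.0, abs(a)):
                raise ValueError("merge heights are not monotone non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def to_linkage(self) -> np.ndarray:
        """scipy-compatible (n-1, 4) linkage matrix."""
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)


def euclidean_distances(table: BucketTable) -> DistanceMatrix:
    """Pairwise Euclidean distances between fingerprint rows."""
    x = np.asarray(table.values, dtype=float)
    if x.shape[0] == 0:
        raise ValueError("empty bucket table")
    bad = [table.sample_ids[i] for i in np.where(~np.isfinite(x).all(axis=1))[0]]
    if bad:
        raise ValueError(f"rows with missing/non-finite values: {bad}")
    return DistanceMatrix(labels=tuple(table.sample_ids), values=squareform(pdist(x)))


def ward_linkage(dist: DistanceMatrix) -> Dendrogram:
    """Agglomerate under Ward's criterion (Lance-Williams on d^2).

    At each step the active pair with the smallest Ward distance merges
    (ties to the lowest (i, j) id pair); distances to the new cluster
    follow d2(k, ij) = ((ni+nk) d2(k,i) + (nj+nk) d2(k,j) - nk d2(i,j))
    / (ni+nj+nk).  Heights are sqrt of the stored squared distances.
    """
    n = len(dist.labels)
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    total = 2 * n - 1
    d2 = np.full((total, total), np.inf)
    d2[:n, :n] = dist.values**2
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    merges = []
    for step in range(n - 1):
        best_i = best_j = -1
        best = np.inf
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                if d2[i, j] < best:  # strict < keeps the lowest (i, j) on ties
                    best, best_i, best_j = d2[i, j], i, j
        new = n + step
        si, sj = sizes[best_i], sizes[best_j]
        for k in active:
            if k in (best_i, best_j):
                continue
            sk = sizes[k]
            val = (
                (si + sk) * d2[best_i, k] + (sj + sk) * d2[best_j, k] - sk * best
            ) / (si + sj + sk)
            d2[new, k] = d2[k, new] = val
        active = [k for k in active if k not in (best_i, best_j)] + [new]
        sizes[new] = si + sj
        merges.append((best_i, best_j, float(np.sqrt(max(best, 0.0))), si + sj))
    return Dendrogram(merges=tuple(merges), leaf_labels=tuple(dist.labels))


def _clusters_at(dend: Dendrogram, k: int) -> list[list[int]]:
    n = dend.n_leaves
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for step, (a, b, _h, _s) in enumerate(dend.merges[: n - k]):
        members[n + step] = members.pop(a) + members.pop(b)
    return sorted(members.values(), key=min)


def cut_tree(dend: Dendrogram, k: int) -> dict[str, int]:
    """Flat clustering with exactly ``k`` clusters.

    Undoes the last k-1 merges; cluster ids are assigned in order of
    each cluster's smallest member leaf index.
    """
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    out = {}
    for cid, leaves in enumerate(_clusters_at(dend, k)):
        for leaf in leaves:
            out[dend.leaf_labels[leaf]] = cid
    return out


def species_recovery(
    assignment: Mapping[str, int], truth: Mapping[str, str]
) -> tuple[int, float]:
    """Count species recovered as pure single-species clusters.

    A species is recovered iff all of its samples share one cluster and
    that cluster contains no sample of any other species.  Returns
    (pure_species_count, purity = recovered / total species).
    """
    if set(assignment) != set(truth):
        raise ValueError("assignment and truth have different sample keys")
    samples_by_species: dict[str, set[str]] = {}
    samples_by_cluster: dict[int, set[str]] = {}
    for sample, cluster in assignment.items():
        samples_by_cluster.setdefault(cluster, set()).add(sample)
        samples_by_species.setdefault(truth[sample], set()).add(sample)
    recovered = 0
    for species, samples in samples_by_species.items():
        clusters = {assignment[s] for s in samples}
        if len(clusters) == 1 and samples_by_cluster[clusters.pop()] == samples:
            recovered += 1
    total = len(samples_by_species)
    return recovered, recovered / total if total else 0.0


def _newick_label(label: str) -> str:
    if any(c in label for c in " ():;,'[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(dend: Dendrogram) -> str:
    """Newick export with branch lengths from merge-height differences.

    Children are ordered smaller-subtree-first (ties: smaller minimum
    leaf index) — purely cosmetic, fixed for reproducibility.
    """
    n = dend.n_leaves
    height = {i: 0.0 for i in range(n)}
    children = {}
    for step, (a, b, h, _s) in enumerate(dend.merges):
        node = n + step
        height[node] = h
        children[node] = (a, b)
    size = {i: 1 for i in range(n)}
    min_leaf = {i: i for i in range(n)}
    for node, (a, b) in children.items():
        size[node] = size[a] + size[b]
        min_leaf[node] = min(min_leaf[a], min_leaf[b])

    def render(node: int, parent_height: float) -> str:
        length = parent_height - height[node]
        if node < n:
            return f"{_newick_label(dend.leaf_labels[node])}:{length:.6g}"
        a, b = sorted(children[node], key=lambda c: (size[c], min_leaf[c]))
        return f"({render(a, height[node])},{render(b, height[node])}):{length:.6g}"

    root = n + len(dend.merges) - 1 if dend.merges else 0
    if not dend.merges:
        return f"{_newick_label(dend.leaf_labels[0])};"
    a, b = sorted(children[root], key=lambda c: (size[c], min_leaf[c]))
    return f"({render(a, height[root])},{render(b, height[root])});"
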