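"""Shape affinity structures: distance matrices, MST, Ward dendrogram.

Group centroid shapes (mean Procrustes coordinates per extant group, plus
each fossil as its own singleton shape) are compared by pairwise
Procrustes superimposition.  The minimum spanning tree links the closest
morphometric neighbours; Ward agglomeration (the Ward.D2 convention,
operating on squared distances) summarises the hierarchy, exported as a
newick string with branch lengths derived from merge heights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .superimposition import AlignedDataset, procrustes_distance_matrix

__all__ = [
    "AffinityResult",
    "group_centroid_shapes",
    "minimum_spanning_tree",
    "ward_cluster",
    "ward_newick",
    "nearest_extant_table",
    "affinity_analysis",
]


def group_centroid_shapes(aligned: AlignedDataset) -> dict[str, np.ndarray]:
    """Mean Procrustes coordinates per extant group; fossils as singletons."""
    shapes: dict[str, list[np.ndarray]] = {}
    for i, s in enumerate(aligned.dataset.specimens):
        key = s.specimen_id if s.is_fossil else s.group
        shapes.setdefault(key, []).append(aligned.procrustes_coords[i])
    return {k: np.mean(v, axis=0) for k, v in shapes.items()}


def _check_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix must be finite")
    return D


def minimum_spanning_tree(
    D: np.ndarray, labels: list[str]
) -> list[tuple[str, str, float]]:
    """Minimum spanning tree by Kruskal's algorithm with deterministic ties.

    Edges are considered in order of (weight, label pair), the label pair
    sorted lexicographically, so equal-weight ties always resolve the same
    way.  Returns n-1 edges as (label_a, label_b, distance).
    """
    D = _check_matrix(D)
    n = len(labels)
    if n != D.shape[0]:
        raise ValueError("labels do not match matrix size")
    edges = sorted(
        (D[i, j], *sorted((labels[i], labels[j])), i, j)
        for i in range(n)
        for j in range(i + 1, n)
    )
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree: list[tuple[str, str, float]] = []
    for w, la, lb, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            tree.append((la, lb, float(w)))
            if len(tree) == n - 1:
                break
    return tree


@dataclass
class Dendrogram:
    """Binary merge tree from agglomerative clustering."""

    labels: list[str]
    linkage_matrix: np.ndarray  # scipy (n-1, 4) format
    heights: np.ndarray  # merge heights, non-decreasing

    def newick(self) -> str:
        return ward_newick(self)


def ward_cluster(D: np.ndarray, labels: list[str], variant: str = "D2") -> Dendrogram:
    """Ward agglomerative clustering of a distance matrix.

    ``variant="D2"`` (default) applies the Lance-Williams Ward update to
    squared distances, the convention of hclust's ward.D2; ``"D"`` applies
    it to the raw distances.  Merge heights are non-decreasing from leaves
    to root.
    """
    D = _check_matrix(D)
    if len(labels) < 2:
        raise ValueError("need at least two items to cluster")
    condensed = squareform(D, checks=False)
    if variant == "D2":
        Z = linkage(condensed, method="ward")
    elif variant == "D":
        # ward.D recurses on raw distances; scipy's ward recurses on squares,
        # so feed sqrt(d) and square the reported heights
        Z = linkage(np.sqrt(condensed), method="ward").copy()
        Z[:, 2] = Z[:, 2] ** 2
    else:
        raise ValueError(f"unknown Ward variant {variant!r}")
    return Dendrogram(labels=list(labels), linkage_matrix=Z, heights=Z[:, 2].copy())


def ward_newick(dendrogram: Dendrogram) -> str:
    """Newick string with branch lengths = parent height - child height."""
    Z = dendrogram.linkage_matrix
    n = len(dendrogram.labels)
    height = {i: 0.0 for i in range(n)}
    node: dict[int, str] = {i: dendrogram.labels[i] for i in range(n)}
    for m, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = height[a]
        lb = height[b]
        node[n + m] = f"({node[a]}:{h - la:.10g},{node[b]}:{h - lb:.10g})"
        height[n + m] = float(h)
    return node[n + len(Z) - 1] + ";"


def nearest_extant_table(
    D: np.ndarray,
    labels: list[str],
    extant: list[str],
    fossils: list[str],
    tie_tol: float = 0.0,
) -> dict[str, list[str]]:
    """Closest extant group per fossil; ties (within tie_tol) all reported."""
    D = _check_matrix(D)
    if set(extant) & set(fossils):
        raise ValueError("extant and fossil label sets must be disjoint")
    idx = {lab: i for i, lab in enumerate(labels)}
    out: dict[str, list[str]] = {}
    for f in fossils:
        dists = {e: D[idx[f], idx[e]] for e in extant}
        dmin = min(dists.values())
        out[f] = sorted(e for e, d in dists.items() if d <= dmin + tie_tol)
    return out


@dataclass
class AffinityResult:
    """Distance matrix over group centroids and fossils plus derived structures."""

    labels: list[str]
    extant_labels: list[str]
    fossil_labels: list[str]
    distance_matrix: np.ndarray
    mst_edges: list[tuple[str, str, float]]
    dendrogram: Dendrogram
    nearest_extant: dict[str, list[str]] = field(default_factory=dict)


def affinity_analysis(
    aligned: AlignedDataset,
    metric: str = "procrustes",
    ward_variant: str = "D2",
) -> AffinityResult:
    """Full affinity analysis of group centroids and fossils.

    ``metric="procrustes"`` re-superimposes centroid shapes pairwise (full
    Procrustes distance); ``"tangent"`` uses Euclidean distance between the
    flattened centroid shapes as aligned (MorphoJ-style comparison).
    """
    shapes = group_centroid_shapes(aligned)
    extant = [g for g in aligned.dataset.groups]
    fossils = [s.specimen_id for s in aligned.dataset.fossils]
    labels = extant + fossils
    arr = [shapes[lab] for lab in labels]
    if metric == "procrustes":
        D = procrustes_distance_matrix(arr)
    elif metric == "tangent":
        flat = np.array([a.ravel() for a in arr])
        diff = flat[:, None, :] - flat[None, :, :]
        D = np.sqrt((diff**2).sum(axis=2))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return AffinityResult(
        labels=labels,
        extant_labels=extant,
        fossil_labels=fossils,
        distance_matrix=D,
        mst_edges=minimum_spanning_tree(D, labels),
        dendrogram=ward_cluster(D, labels, variant=ward_variant),
        nearest_extant=nearest_extant_table(D, labels, extant, fossils),
    )
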