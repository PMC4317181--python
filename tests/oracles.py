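"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (loops, grids, exhaustive
enumeration) and shares no code path with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_centroid_size(points) -> float:
    """Double-loop centroid size: sqrt of summed squared deviation from centroid."""
    pts = [list(map(float, p)) for p in points]
    k = len(pts)
    mean = [sum(p[a] for p in pts) / k for a in range(3)]
    total = 0.0
    for p in pts:
        for a in range(3):
            total += (p[a] - mean[a]) ** 2
    return math.sqrt(total)


def grid_search_planar_procrustes(A: np.ndarray, B: np.ndarray, step_deg: float = 0.001) -> float:
    """Full Procrustes distance between planar (z=0) configs by rotation grid.

    Scans in-plane rotations of the unit preshape of A onto B at
    ``step_deg`` resolution, both as-is and composed with a proper 180-deg
    rotation about x (which acts as an in-plane reflection on planar
    shapes, so all proper 3D rotations mapping the plane to itself are
    covered).  For each angle the optimal scaling is applied in closed
    form; the minimum distance over the grid is returned.
    """

    def preshape(X):
        Xc = X - X.mean(axis=0)
        return Xc / np.sqrt((Xc**2).sum())

    Pa, Pb = preshape(np.asarray(A, float)), preshape(np.asarray(B, float))
    flip = np.diag([1.0, -1.0, -1.0])  # proper rotation, det +1
    angles = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    best = np.inf
    cos, sin = np.cos(angles), np.sin(angles)
    for base in (Pa, Pa @ flip):
        x, y = base[:, 0], base[:, 1]
        # rotated coords: (x cos - y sin, x sin + y cos); z unchanged
        # trace(B^T A_rot) as a function of the angle, vectorised over grid
        t1 = float(x @ Pb[:, 0] + y @ Pb[:, 1])
        t2 = float(x @ Pb[:, 1] - y @ Pb[:, 0])
        tz = float(base[:, 2] @ Pb[:, 2])
        trace = t1 * cos + t2 * sin + tz
        # optimal scaling beta = trace; residual 1 - trace^2
        d2 = 1.0 - np.maximum(trace, 0.0) ** 2
        best = min(best, float(np.sqrt(np.maximum(d2.min(), 0.0))))
    return best


def prufer_mst_weight(D: np.ndarray) -> float:
    """Minimum spanning tree weight by exhaustive enumeration.

    Every labelled spanning tree of the complete graph on n vertices
    corresponds to a Prüfer sequence of length n-2; all n^(n-2) trees are
    decoded and weighed.
    """
    n = D.shape[0]
    if n == 2:
        return float(D[0, 1])
    best = np.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        degree = [1] * n
        for v in seq:
            degree[v] += 1
        weight = 0.0
        deg = list(degree)
        seq_iter = list(seq)
        leaves = sorted(i for i in range(n) if deg[i] == 1)
        import heapq

        heapq.heapify(leaves)
        for v in seq_iter:
            leaf = heapq.heappop(leaves)
            weight += D[leaf, v]
            deg[v] -= 1
            if deg[v] == 1:
                heapq.heappush(leaves, v)
        a = heapq.heappop(leaves)
        b = heapq.heappop(leaves)
        weight += D[a, b]
        if weight < best:
            best = weight
    return float(best)


def naive_ward_d2(D: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """O(n^3) Ward agglomeration (D2 convention) via Lance-Williams on d^2.

    Returns the merge sequence as (cluster_a, cluster_b, height) with
    clusters as frozensets of leaf indices and heights on the distance
    (not squared) scale.
    """
    n = D.shape[0]
    clusters: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    d2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = float(D[i, j] ** 2)

    def get(i, j):
        return d2[(i, j) if i < j else (j, i)]

    merges = []
    next_id = n
    active = list(range(n))
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                v = get(i, j)
                if best is None or v < best[0]:
                    best = (v, i, j)
        v, i, j = best
        merges.append((clusters[i], clusters[j], math.sqrt(v)))
        ni, nj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            upd = ((ni + nk) * get(i, k) + (nj + nk) * get(j, k) - nk * v) / (ni + nj + nk)
            d2[(min(k, new), max(k, new))] = upd
        clusters[new] = clusters[i] | clusters[j]
        sizes[new] = ni + nj
        active = [k for k in active if k not in (i, j)] + [new]
    return merges


def brute_group_mean_eigenvalues(mean_vectors: np.ndarray) -> np.ndarray:
    """Eigenvalues of the explicit covariance matrix of a few mean vectors.

    Builds the full p x p covariance with loops over pairs of coordinates
    (denominator g-1) and eigendecomposes it directly.  Only usable for
    small p.
    """
    M = np.asarray(mean_vectors, float)
    g, p = M.shape
    grand = M.mean(axis=0)
    C = np.zeros((p, p))
    for a in range(p):
        for b in range(p):
            s = 0.0
            for i in range(g):
                s += (M[i, a] - grand[a]) * (M[i, b] - grand[b])
            C[a, b] = s / (g - 1)
    vals = np.linalg.eigvalsh(C)
    return np.sort(vals)[::-1]
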