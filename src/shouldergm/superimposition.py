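"""Procrustes superimposition: pairwise alignment, GPA, tangent projection.

Shape here is what remains of a landmark configuration after removing
location, scale and orientation.  Configurations are centred, scaled to
unit centroid size (the *preshape*), and rotated onto a reference by the
Kabsch/SVD solution.  Generalized Procrustes analysis (GPA) iterates
rotation-to-consensus and consensus update until the consensus stabilises;
aligned coordinates are then projected orthogonally onto the linear space
tangent to the shape manifold at the consensus so ordinary multivariate
statistics apply.

The Procrustes distance between two shapes is the full Procrustes
distance: the root summed squared coordinate difference between the unit
preshapes after optimal rotation *and* optimal scaling of one onto the
other, d = sqrt(1 - s^2) with s the sum of singular values of the
cross-covariance.  Reflections are disallowed by default (anatomical data;
left elements are mirrored explicitly upstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landmark_io import LandmarkConfiguration, LandmarkDataset

__all__ = [
    "AlignedDataset",
    "centroid_size",
    "align_pair",
    "gpa",
    "tangent_project",
    "procrustes_distance",
    "procrustes_distance_matrix",
]


def _as_coords(config: LandmarkConfiguration | np.ndarray) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return config.coords
    return np.asarray(config, dtype=float)


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Centroid size: root summed squared deviation of points from their centroid.

    CS = sqrt(sum_i ||x_i - xbar||^2).  Invariant to rotation, translation
    and mirroring; scales linearly with isotropic scaling.
    """
    X = _as_coords(config)
    centred = X - X.mean(axis=0)
    cs = float(np.sqrt((centred**2).sum()))
    if cs == 0.0:
        raise ValueError("degenerate configuration: all points coincide")
    return cs


def _preshape(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Centre and scale to unit centroid size; return (preshape, centroid, cs)."""
    centroid = X.mean(axis=0)
    centred = X - centroid
    cs = np.sqrt((centred**2).sum())
    if cs == 0.0:
        raise ValueError("degenerate configuration: all points coincide")
    return centred / cs, centroid, float(cs)


def _optimal_rotation(A: np.ndarray, B: np.ndarray, allow_reflection: bool) -> tuple[np.ndarray, float]:
    """Rotation R minimising ||A @ R - B||; returns (R, trace of singular values).

    With ``allow_reflection`` False the determinant of R is forced to +1 by
    negating the smallest singular direction when needed.
    """
    M = A.T @ B
    U, s, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt))
    if not allow_reflection and d < 0:
        U = U.copy()
        U[:, -1] *= -1
        s = s.copy()
        s[-1] *= -1
    R = U @ Vt
    return R, float(s.sum())


def align_pair(
    reference: LandmarkConfiguration | np.ndarray,
    target: LandmarkConfiguration | np.ndarray,
    allow_reflection: bool = False,
    scale: bool = True,
) -> tuple[np.ndarray, float]:
    """Superimpose ``target`` onto ``reference``; return (aligned coords, distance).

    The aligned coordinates are the optimally translated, rotated and (with
    ``scale``) scaled target expressed in the reference's original frame.
    The returned distance is the full Procrustes distance between the unit
    preshapes (partial/rotation-only if ``scale`` is False).
    """
    Xr, Xt = _as_coords(reference), _as_coords(target)
    if Xr.shape != Xt.shape:
        raise ValueError(f"landmark count mismatch: {Xr.shape} vs {Xt.shape}")
    Pr, cr, sr = _preshape(Xr)
    Pt, ct, st = _preshape(Xt)
    R, trace = _optimal_rotation(Pt, Pr, allow_reflection)
    # optimal scaling of the unit-preshape target onto the reference is
    # beta = trace; the distance is evaluated from the residual itself
    # (rather than sqrt(1 - trace^2)) to avoid cancellation near zero
    beta = trace if scale else 1.0
    residual = beta * (Pt @ R) - Pr
    distance = float(np.sqrt((residual**2).sum()))
    aligned = (beta * (Pt @ R)) * sr + cr
    return aligned, distance


def procrustes_distance(
    a: LandmarkConfiguration | np.ndarray,
    b: LandmarkConfiguration | np.ndarray,
    allow_reflection: bool = False,
    scale: bool = True,
) -> float:
    """Full Procrustes distance between two configurations."""
    return align_pair(a, b, allow_reflection=allow_reflection, scale=scale)[1]


def procrustes_distance_matrix(
    shapes: list[LandmarkConfiguration] | list[np.ndarray] | np.ndarray,
    allow_reflection: bool = False,
    scale: bool = True,
) -> np.ndarray:
    """Symmetric zero-diagonal matrix of pairwise Procrustes distances."""
    coords = [_as_coords(s) for s in shapes]
    n = len(coords)
    if n < 2:
        raise ValueError("need at least two shapes")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = procrustes_distance(
                coords[i], coords[j], allow_reflection=allow_reflection, scale=scale
            )
            D[i, j] = D[j, i] = d
    return D


@dataclass
class AlignedDataset:
    """Output of GPA over a landmark dataset.

    ``procrustes_coords`` are unit-centroid-size, origin-centred, consensus-
    rotated configurations; ``tangent_coords`` their flattened orthogonal
    projections onto the tangent hyperplane at the consensus (filled by
    :func:`tangent_project`).  ``centroid_sizes`` stores each specimen's CS
    before scaling.
    """

    dataset: LandmarkDataset
    consensus: np.ndarray  # (k, 3), unit CS, centred
    procrustes_coords: np.ndarray  # (n, k, 3)
    centroid_sizes: np.ndarray  # (n,)
    rotations: np.ndarray  # (n, 3, 3) raw-centred-scaled -> aligned
    iterations: int
    converged: bool
    objective_trace: list[float] = field(default_factory=list)
    tangent_coords: np.ndarray | None = None  # (n, 3k)

    @property
    def specimen_ids(self) -> list[str]:
        return [s.specimen_id for s in self.dataset.specimens]

    @property
    def k(self) -> int:
        return self.consensus.shape[0]

    def tangent(self) -> np.ndarray:
        if self.tangent_coords is None:
            raise ValueError("tangent coordinates not computed; call tangent_project first")
        return self.tangent_coords

    def tangent_by_id(self) -> dict[str, np.ndarray]:
        return dict(zip(self.specimen_ids, self.tangent()))


def gpa(
    dataset: LandmarkDataset,
    tol: float = 1e-10,
    max_iter: int = 100,
    allow_reflection: bool = False,
    project_tangent: bool = True,
) -> AlignedDataset:
    """Generalized Procrustes analysis.

    Each configuration is centred and scaled to unit centroid size, then
    iteratively rotated onto the running consensus (the normalised mean of
    the aligned configurations) until the consensus root-mean-square change
    falls below ``tol`` or ``max_iter`` is reached.  The summed squared
    distance of aligned configurations to their mean is non-increasing
    across iterations.
    """
    n = len(dataset.specimens)
    if n < 2:
        raise ValueError("GPA requires at least two specimens")
    raw = dataset.coords_array()
    pre = np.empty_like(raw)
    sizes = np.empty(n)
    for i in range(n):
        pre[i], _, sizes[i] = _preshape(raw[i])

    aligned = pre.copy()
    rotations = np.tile(np.eye(3), (n, 1, 1))
    # initial consensus: first specimen's preshape (arbitrary; result is
    # invariant to the choice up to a global rotation)
    consensus = pre[0]
    objective_trace: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            R, _ = _optimal_rotation(pre[i], consensus, allow_reflection)
            rotations[i] = R
            aligned[i] = pre[i] @ R
        mean = aligned.mean(axis=0)
        objective_trace.append(float(((aligned - mean) ** 2).sum()))
        new_consensus = mean / np.sqrt((mean**2).sum())
        change = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        if change < tol:
            converged = True
            break

    result = AlignedDataset(
        dataset=dataset,
        consensus=consensus,
        procrustes_coords=aligned,
        centroid_sizes=sizes,
        rotations=rotations,
        iterations=iterations,
        converged=converged,
        objective_trace=objective_trace,
    )
    if project_tangent:
        result = tangent_project(result)
    return result


def shape_tangent_component(vector: np.ndarray, shape: np.ndarray) -> np.ndarray:
    """Project a landmark-space displacement onto the shape tangent space at ``shape``.

    Removes the components along the similarity orbit of ``shape``:
    translations, uniform scaling, and infinitesimal rotations.  What
    remains is the part of the displacement that is actual shape change -
    the only part any Procrustes-based analysis can see or recover.
    ``vector`` may be (k, 3) or flat; the result matches the input shape.
    """
    X = np.asarray(shape, dtype=float)
    k = X.shape[0]
    v = np.asarray(vector, dtype=float)
    flat_in = v.ndim == 1
    v = v.reshape(k, 3).copy()
    v -= v.mean(axis=0)  # translations
    P, _, _ = _preshape(X)
    basis = [P.ravel()]  # uniform scaling direction
    gen = (
        np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]]),
        np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 0.0], [-1.0, 0.0, 0.0]]),
        np.array([[0.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]]),
    )
    for g in gen:
        basis.append((P @ g.T).ravel())
    flat = v.ravel()
    # Gram-Schmidt over the (at most 4-dimensional) orbit basis
    ortho: list[np.ndarray] = []
    for b in basis:
        for prev in ortho:
            b = b - (b @ prev) * prev
        n = np.linalg.norm(b)
        if n > 1e-12:
            ortho.append(b / n)
    for b in ortho:
        flat = flat - (flat @ b) * b
    return flat if flat_in else flat.reshape(k, 3)


def tangent_project(aligned: AlignedDataset) -> AlignedDataset:
    """Project aligned configurations onto the tangent hyperplane at the consensus.

    Each flattened Procrustes configuration x (3k-vector) is orthogonally
    projected onto the affine hyperplane {y : y.c = |c|^2} through the unit
    consensus c:  x_t = x + (1 - x.c) c.  The consensus is a fixed point
    and the projection is idempotent; for shapes near the consensus the
    correction is O(d^2) in the Procrustes distance d.
    """
    c = aligned.consensus.ravel()
    X = aligned.procrustes_coords.reshape(len(aligned.centroid_sizes), -1)
    Xt = X + np.outer(1.0 - X @ c, c)
    aligned.tangent_coords = Xt
    return aligned
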