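"""Sliding of curve semilandmarks by Procrustes-distance minimization.

Semilandmarks carry no point-wise homology along their curve, so their
arbitrary along-curve placement is treated as nuisance variation: each one
is allowed to slide along the local tangent line of its anchored curve to
the position minimising the specimen's squared Procrustes distance to the
current sample consensus.  The tangent at a semilandmark is the central
difference of its two curve neighbours (an anchor counts as a neighbour).
Because the objective is quadratic along the line, the optimal slide is
the closed-form orthogonal projection of the residual onto the tangent
direction - no numeric line search.

The outer loop alternates GPA and per-specimen, per-semilandmark sliding
until the total squared Procrustes distance to the consensus stops
improving.  Slid positions are mapped back to each specimen's raw frame,
so type-II landmark coordinates are returned bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .landmark_io import Curve, LandmarkConfiguration, LandmarkDataset, LandmarkProtocol
from .superimposition import AlignedDataset, gpa

__all__ = ["SlideResult", "curve_tangent", "slide_dataset"]


@dataclass
class SlideResult:
    """Dataset with slid semilandmarks plus the optimisation trace."""

    dataset: LandmarkDataset
    objective_trace: list[float]  # total squared Procrustes distance per outer iteration
    n_outer_iterations: int
    aligned: AlignedDataset  # GPA of the slid dataset


def _neighbours(curve: Curve, sl_label: str) -> tuple[str, str]:
    pts = curve.points
    i = pts.index(sl_label)
    return pts[i - 1], pts[i + 1]


def curve_tangent(
    config: LandmarkConfiguration | np.ndarray,
    curve: Curve,
    sl_label: str,
    protocol: LandmarkProtocol,
) -> np.ndarray:
    """Unit tangent at a semilandmark: normalised difference of its curve neighbours."""
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config)
    if sl_label not in curve.semilandmarks:
        raise ValueError(f"{sl_label!r} is not a semilandmark of this curve")
    prev_lab, next_lab = _neighbours(curve, sl_label)
    diff = coords[protocol.index_of(next_lab)] - coords[protocol.index_of(prev_lab)]
    norm = np.linalg.norm(diff)
    if norm == 0.0:
        raise ValueError(
            f"zero-length tangent at {sl_label!r}: neighbours {prev_lab!r}/{next_lab!r} coincide"
        )
    return diff / norm


def slide_dataset(
    dataset: LandmarkDataset,
    protocol: LandmarkProtocol | None = None,
    tol: float = 1e-8,
    max_outer: int = 10,
    gpa_tol: float = 1e-10,
) -> SlideResult:
    """Slide all curve semilandmarks to minimise Procrustes distance to the mean.

    Raises if the protocol declares no curves.  Aborts with a diagnostic if
    the objective increases beyond tolerance (divergence), which indicates
    an ill-conditioned curve (e.g. coincident anchors).
    """
    protocol = protocol or dataset.protocol
    if not protocol.curves:
        raise ValueError(f"protocol {protocol.name!r} declares no slideable curves")
    sl_entries = [
        (protocol.index_of(sl), curve, sl)
        for curve in protocol.curves
        for sl in curve.semilandmarks
    ]

    work = [s.coords.copy() for s in dataset.specimens]
    current = dataset
    trace: list[float] = []
    passes = 0
    aligned = gpa(current, tol=gpa_tol, project_tangent=False)
    for _outer in range(1, max_outer + 1):
        consensus = aligned.consensus
        objective = float(((aligned.procrustes_coords - consensus) ** 2).sum())
        trace.append(objective)
        if len(trace) >= 2:
            if trace[-1] > trace[-2] + 1e-9 * max(1.0, trace[-2]):
                raise RuntimeError(
                    f"sliding diverged at outer iteration {_outer}: objective "
                    f"{trace[-2]:.6e} -> {trace[-1]:.6e}"
                )
            if trace[-2] - trace[-1] < tol * max(1.0, trace[-2]):
                break

        # slide each semilandmark independently, in the Procrustes frame,
        # then map the new position back into the specimen's raw frame
        moved = [idx for idx, _, _ in sl_entries]
        for i in range(len(current.specimens)):
            proc = aligned.procrustes_coords[i]
            new_proc = proc.copy()
            for idx, curve, sl in sl_entries:
                t = curve_tangent(proc, curve, sl, protocol)
                residual = consensus[idx] - proc[idx]
                step = float(residual @ t)  # closed-form 1D minimiser
                new_proc[idx] = proc[idx] + step * t
            # raw = proc @ R^T * cs + centroid  (inverse of the GPA map)
            R = aligned.rotations[i]
            cs = aligned.centroid_sizes[i]
            centroid = current.specimens[i].coords.mean(axis=0)
            work[i] = current.specimens[i].coords.copy()
            work[i][moved] = (new_proc[moved] @ R.T) * cs + centroid
        passes += 1

        current = LandmarkDataset(
            protocol=dataset.protocol,
            specimens=[
                replace(s, coords=work[i].copy(), covariates=dict(s.covariates))
                for i, s in enumerate(dataset.specimens)
            ],
            provenance=dataset.provenance,
        )
        aligned = gpa(current, tol=gpa_tol, project_tangent=False)

    from .superimposition import tangent_project

    aligned = tangent_project(aligned)
    return SlideResult(
        dataset=current,
        objective_trace=trace,
        n_outer_iterations=passes,
        aligned=aligned,
    )
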