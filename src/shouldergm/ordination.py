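"""Ordination: between-group PCA, size-shape PCA, shape reconstruction, ellipses.

Between-group PCA (bgPCA) summarises among-group shape differences by an
eigendecomposition of the covariance of the *group mean* tangent vectors,
each group weighted equally regardless of sample size.  Individual
specimens - and singleton fossil specimens, which never influence the
axes - are then scored on those axes by projecting their deviation from
the grand mean (the unweighted mean of group means).  For g groups at most
g - 1 components have nonzero variance, and the percent-variance column
sums to 100 over those components.

Size-shape PCA is an ordinary covariance PCA of the residuals from the
shape-on-centroid-size regression, fossils included, used to examine
affinities once the linear allometric component is removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .landmark_io import LandmarkConfiguration
from .superimposition import AlignedDataset

__all__ = [
    "BgPCAResult",
    "PCAResult",
    "EllipseSpec",
    "bgpca",
    "project_specimens",
    "size_shape_pca",
    "reconstruct_shape",
    "equal_frequency_ellipse",
]

_EIGENVALUE_FLOOR = 1e-12


@dataclass
class BgPCAResult:
    """Between-group PCA decomposition with individual and fossil scores."""

    group_means: dict[str, np.ndarray]
    grand_mean: np.ndarray
    eigenvectors: np.ndarray  # (n_components, p) rows orthonormal
    eigenvalues: np.ndarray  # (n_components,) descending
    pct_variance: np.ndarray
    cumulative_pct: np.ndarray
    scores: dict[str, np.ndarray]  # extant specimen id -> component scores
    projected_scores: dict[str, np.ndarray] = field(default_factory=dict)  # fossils
    specimen_groups: dict[str, str] = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def scores_matrix(self) -> tuple[list[str], np.ndarray]:
        ids = list(self.scores)
        return ids, np.array([self.scores[i] for i in ids])


@dataclass
class PCAResult:
    """Ordinary covariance PCA (used for size-shape PCA of residuals)."""

    mean: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    scores: dict[str, np.ndarray]


@dataclass
class EllipseSpec:
    """A bivariate equal-frequency ellipse in score space."""

    center: np.ndarray  # (2,)
    semi_axes: np.ndarray  # (2,) major, minor
    orientation: float  # radians, major axis vs first score axis
    level: float

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_axes[0] * self.semi_axes[1])


def _group_tangent_means(
    aligned: AlignedDataset, groups: list[str] | None = None
) -> dict[str, np.ndarray]:
    tangent = aligned.tangent_by_id()
    by_group: dict[str, list[np.ndarray]] = {}
    for s in aligned.dataset.extant:
        by_group.setdefault(s.group, []).append(tangent[s.specimen_id])
    if groups is not None:
        missing = [g for g in groups if g not in by_group]
        if missing:
            raise ValueError(f"groups with no extant specimens: {missing}")
        by_group = {g: by_group[g] for g in groups}
    return {g: np.mean(v, axis=0) for g, v in by_group.items()}


def bgpca(aligned: AlignedDataset, groups: list[str] | None = None) -> BgPCAResult:
    """Between-group PCA of an aligned dataset.

    Fossil specimens (group ``fossil:<name>``) are excluded from the group
    means and the eigendecomposition, then projected post hoc onto the
    extant-defined axes.
    """
    means = _group_tangent_means(aligned, groups)
    g = len(means)
    if g < 2:
        raise ValueError(f"bgPCA requires at least two groups, found {g}")
    labels = list(means)
    M = np.array([means[g_] for g_ in labels])  # (g, p)
    grand_mean = M.mean(axis=0)
    centred = M - grand_mean
    # covariance of group means (denominator g-1), eigendecomposition via SVD
    U, sv, Vt = np.linalg.svd(centred, full_matrices=False)
    eigenvalues = sv**2 / (g - 1)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    eigenvectors = Vt[order]
    nonzero = eigenvalues > _EIGENVALUE_FLOOR * max(eigenvalues.max(), 1.0)
    eigenvalues = eigenvalues[nonzero]
    eigenvectors = eigenvectors[nonzero]
    total = eigenvalues.sum()
    pct = 100.0 * eigenvalues / total
    result = BgPCAResult(
        group_means=means,
        grand_mean=grand_mean,
        eigenvectors=eigenvectors,
        eigenvalues=eigenvalues,
        pct_variance=pct,
        cumulative_pct=np.cumsum(pct),
        scores={},
        specimen_groups={
            s.specimen_id: s.group for s in aligned.dataset.specimens
        },
    )
    tangent = aligned.tangent_by_id()
    for s in aligned.dataset.extant:
        result.scores[s.specimen_id] = project_specimens(result, tangent[s.specimen_id])
    for s in aligned.dataset.fossils:
        result.projected_scores[s.specimen_id] = project_specimens(
            result, tangent[s.specimen_id]
        )
    return result


def project_specimens(result: BgPCAResult | PCAResult, vectors: np.ndarray) -> np.ndarray:
    """Score tangent vectors on fitted axes: (x - mean) @ eigenvectors^T.

    Accepts a single p-vector or an (n, p) stack; projection is linear, so
    a convex combination of shapes maps to the same combination of scores.
    """
    mean = result.grand_mean if isinstance(result, BgPCAResult) else result.mean
    X = np.asarray(vectors, dtype=float)
    if X.shape[-1] != mean.shape[0]:
        raise ValueError(
            f"dimension mismatch: vectors have {X.shape[-1]} coordinates, fit has {mean.shape[0]}"
        )
    return (X - mean) @ result.eigenvectors.T


def size_shape_pca(
    residuals: dict[str, np.ndarray] | np.ndarray,
    ids: list[str] | None = None,
) -> PCAResult:
    """Covariance PCA of shape-regression residuals (fossils included)."""
    if isinstance(residuals, dict):
        ids = list(residuals)
        X = np.array([residuals[i] for i in ids])
    else:
        X = np.asarray(residuals, dtype=float)
        ids = ids or [f"specimen_{i + 1}" for i in range(len(X))]
    n = X.shape[0]
    if n < 3:
        raise ValueError("size-shape PCA requires at least three specimens")
    mean = X.mean(axis=0)
    centred = X - mean
    U, sv, Vt = np.linalg.svd(centred, full_matrices=False)
    eigenvalues = sv**2 / (n - 1)
    keep = eigenvalues > _EIGENVALUE_FLOOR * max(eigenvalues.max(), 1.0)
    eigenvalues, Vt = eigenvalues[keep], Vt[keep]
    pct = 100.0 * eigenvalues / eigenvalues.sum()
    scores_mat = centred @ Vt.T
    return PCAResult(
        mean=mean,
        eigenvectors=Vt,
        eigenvalues=eigenvalues,
        pct_variance=pct,
        scores={i: scores_mat[j] for j, i in enumerate(ids)},
    )


def reconstruct_shape(
    result: BgPCAResult | PCAResult,
    score_point: np.ndarray,
    k: int | None = None,
) -> np.ndarray:
    """Landmark-space shape at a point in score space.

    mean + sum_c score_c * eigenvector_c, reshaped (k, 3).  A zero score
    returns the mean shape; reconstruction from a full score vector inverts
    projection on the span of the retained axes.
    """
    mean = result.grand_mean if isinstance(result, BgPCAResult) else result.mean
    s = np.zeros(result.eigenvectors.shape[0])
    score_point = np.atleast_1d(np.asarray(score_point, dtype=float))
    s[: len(score_point)] = score_point
    flat = mean + s @ result.eigenvectors
    k = k or flat.shape[0] // 3
    return flat.reshape(k, 3)


def equal_frequency_ellipse(scores_2d: np.ndarray, level: float = 0.95) -> EllipseSpec:
    """Equal-frequency ellipse of a group's bivariate scores.

    Under a Gaussian model the squared Mahalanobis radius is chi-square
    with 2 df, so the ellipse covering ``level`` of the distribution has
    semi-axes sqrt(lambda_i * chi2_quantile(level, 2)) along the covariance
    eigenvectors.
    """
    X = np.asarray(scores_2d, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("scores_2d must be (n, 2)")
    if X.shape[0] < 3:
        raise ValueError("need at least three specimens for an ellipse")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    center = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[-1] <= _EIGENVALUE_FLOOR * max(evals[0], 1.0):
        import warnings

        warnings.warn("singular score covariance: degenerate ellipse", stacklevel=2)
        evals = np.maximum(evals, 0.0)
    q = stats.chi2.ppf(level, df=2)
    return EllipseSpec(
        center=center,
        semi_axes=np.sqrt(evals * q),
        orientation=float(np.arctan2(evecs[1, 0], evecs[0, 0])),
        level=level,
    )


def group_score_ellipses(
    result: BgPCAResult, components: tuple[int, int] = (0, 1), level: float = 0.95
) -> dict[str, EllipseSpec]:
    """Per-group equal-frequency ellipses in a plane of bgPCA score space."""
    by_group: dict[str, list[np.ndarray]] = {}
    for sid, sc in result.scores.items():
        by_group.setdefault(result.specimen_groups[sid], []).append(
            sc[list(components)]
        )
    return {
        g: equal_frequency_ellipse(np.array(v), level=level)
        for g, v in by_group.items()
        if len(v) >= 3
    }
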