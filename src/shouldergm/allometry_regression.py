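"""Multivariate regression of shape on a scalar covariate.

Shape (the full tangent-coordinate vector) is regressed jointly on one
scalar - centroid size for allometry, or the humeral torsion angle in
degrees (90 deg-offset convention for posterior-facing heads).  The fit is
ordinary least squares per coordinate, which for a single predictor is

    b = cov(x, y_j) / var(x)        per tangent coordinate j,

and the percentage of shape variance explained is the predicted sum of
squares over the total sum of squares, summed across all coordinates.
Significance is assessed by permuting the covariate against the shapes
and counting permuted %variance values at least as large as observed
(count-based p with the +1 correction).  The regression score of a
specimen is the projection of its centred shape onto the unit coefficient
vector - the axis of the "shape variable most associated" with the
covariate.

Fossil (singleton) specimens never enter the fit; their residuals and
scores are computed against the extant-fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .superimposition import AlignedDataset

__all__ = [
    "RegressionResult",
    "shape_regression",
    "permutation_pvalue",
    "predict_shape_at",
    "torsion_summary_table",
]


@dataclass
class RegressionResult:
    """Multivariate shape-on-scalar least-squares fit."""

    covariate_name: str
    intercept_shape: np.ndarray  # (p,) tangent vector at covariate 0
    coefficient_vector: np.ndarray  # (p,) shape change per covariate unit
    pct_variance_explained: float
    regression_scores: dict[str, float]
    residuals: dict[str, np.ndarray]
    fit_ids: list[str]
    covariate_values: dict[str, float]
    permutation_p: float | None = None
    n_permutations: int = 0
    seed: int | None = None
    _fit_matrix: np.ndarray | None = field(default=None, repr=False)
    _fit_covariate: np.ndarray | None = field(default=None, repr=False)

    @property
    def mean_shape(self) -> np.ndarray:
        x = self._fit_covariate
        assert x is not None
        return self.intercept_shape + self.coefficient_vector * x.mean()


def _pct_variance(X: np.ndarray, x: np.ndarray) -> float:
    """%variance of shape matrix X (n, p) explained by OLS on scalar x."""
    xc = x - x.mean()
    Xc = X - X.mean(axis=0)
    sxx = float(xc @ xc)
    beta = (xc @ Xc) / sxx  # (p,)
    ss_pred = float(sxx * (beta @ beta))
    ss_tot = float((Xc**2).sum())
    if ss_tot == 0.0:
        return 0.0
    return 100.0 * ss_pred / ss_tot


def shape_regression(
    aligned: AlignedDataset,
    covariate: dict[str, float] | str,
    covariate_name: str | None = None,
    fit_ids: list[str] | None = None,
) -> RegressionResult:
    """Fit shape ~ covariate on the extant specimens.

    ``covariate`` is either a per-specimen {id: value} map, the string
    ``"centroid_size"`` (computed from the alignment), or the name of a
    covariate carried by the specimens (e.g. ``"torsion_deg"``).  Specimens
    without a value are excluded from the fit; fossils are always excluded
    but receive residuals and scores against the extant fit.
    """
    ds = aligned.dataset
    tangent = aligned.tangent_by_id()
    if isinstance(covariate, str):
        name = covariate_name or covariate
        if covariate == "centroid_size":
            values = dict(zip(aligned.specimen_ids, aligned.centroid_sizes))
        else:
            values = {
                s.specimen_id: s.covariates[covariate]
                for s in ds.specimens
                if covariate in s.covariates
            }
    else:
        name = covariate_name or "covariate"
        values = dict(covariate)
    values = {k: float(v) for k, v in values.items() if np.isfinite(v)}

    extant_ids = {s.specimen_id for s in ds.extant}
    if fit_ids is None:
        fit_ids = [i for i in aligned.specimen_ids if i in extant_ids and i in values]
    else:
        missing = [i for i in fit_ids if i not in values]
        if missing:
            raise ValueError(f"covariate undefined for fit specimens: {missing}")
    if len(fit_ids) < 3:
        raise ValueError(f"need at least three specimens with {name!r} to fit")

    X = np.array([tangent[i] for i in fit_ids])
    x = np.array([values[i] for i in fit_ids])
    if np.ptp(x) == 0.0:
        raise ValueError(f"covariate {name!r} has zero variance over the fit set")

    xc = x - x.mean()
    Xc = X - X.mean(axis=0)
    sxx = float(xc @ xc)
    beta = (xc @ Xc) / sxx
    intercept = X.mean(axis=0) - beta * x.mean()
    pct = _pct_variance(X, x)

    beta_norm = np.linalg.norm(beta)
    unit = beta / beta_norm if beta_norm > 0 else beta
    mean_shape = X.mean(axis=0)

    scores: dict[str, float] = {}
    residuals: dict[str, np.ndarray] = {}
    for sid in aligned.specimen_ids:
        v = tangent[sid]
        scores[sid] = float((v - mean_shape) @ unit)
        if sid in values:
            predicted = intercept + beta * values[sid]
            residuals[sid] = v - predicted
        else:
            residuals[sid] = v - mean_shape

    return RegressionResult(
        covariate_name=name,
        intercept_shape=intercept,
        coefficient_vector=beta,
        pct_variance_explained=pct,
        regression_scores=scores,
        residuals=residuals,
        fit_ids=list(fit_ids),
        covariate_values=values,
        _fit_matrix=X,
        _fit_covariate=x,
    )


def permutation_pvalue(
    result: RegressionResult, n_perm: int = 10_000, seed: int = 0
) -> float:
    """Permutation p-value for the %variance explained.

    p = (1 + #{permuted %var >= observed}) / (1 + n_perm); deterministic
    given the seed.  The result object is annotated in place.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    X, x = result._fit_matrix, result._fit_covariate
    if X is None or x is None:
        raise ValueError("result does not carry its fit data")
    rng = np.random.default_rng(seed)
    observed = result.pct_variance_explained
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(x)
        if _pct_variance(X, perm) >= observed - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    result.permutation_p = p
    result.n_permutations = n_perm
    result.seed = seed
    return p


def predict_shape_at(result: RegressionResult, covariate_value: float) -> np.ndarray:
    """Predicted landmark shape at a covariate value, reshaped (k, 3)."""
    flat = result.intercept_shape + covariate_value * result.coefficient_vector
    return flat.reshape(-1, 3)


def torsion_summary_table(
    values_by_group: dict[str, list[float] | np.ndarray],
    fossils: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-group torsion summary: mean, N, sample SD, plus an overall row.

    Torsion is in degrees under the 90 deg-offset convention (a posteriorly
    facing head scores 90, not 0).  Fossils are listed individually with
    N = 1 and no SD.  Empty groups are dropped with a warning.
    """
    rows = []
    all_values: list[float] = []
    for group, vals in values_by_group.items():
        v = np.asarray(list(vals), dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            import warnings

            warnings.warn(f"group {group!r} has no torsion values; dropped", stacklevel=2)
            continue
        rows.append(
            {
                "group": group,
                "mean": v.mean(),
                "N": int(v.size),
                "SD": v.std(ddof=1) if v.size > 1 else np.nan,
            }
        )
        all_values.extend(v.tolist())
    overall = np.asarray(all_values)
    rows.append(
        {
            "group": "Total",
            "mean": overall.mean() if overall.size else np.nan,
            "N": int(overall.size),
            "SD": overall.std(ddof=1) if overall.size > 1 else np.nan,
        }
    )
    if fossils:
        for name, val in fossils.items():
            rows.append({"group": name, "mean": float(val), "N": 1, "SD": np.nan})
    return pd.DataFrame(rows, columns=["group", "mean", "N", "SD"])
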