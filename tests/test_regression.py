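"""Shape-on-scalar regression: fit quality, permutation test, torsion table."""

import numpy as np
import pytest
from scipy import stats

from shouldergm.allometry_regression import (
    permutation_pvalue,
    predict_shape_at,
    shape_regression,
    torsion_summary_table,
)
from shouldergm.landmark_io import LandmarkConfiguration, LandmarkDataset
from shouldergm.superimposition import AlignedDataset

from conftest import simple_protocol


def _aligned_from_tangent(X, ids=None, groups=None, covs=None):
    """Wrap a raw (n, 3k) tangent matrix into an AlignedDataset directly,
    bypassing GPA, so regressions can be tested against exact constructions."""
    n, p = X.shape
    k = p // 3
    ids = ids or [f"s{i + 1}" for i in range(n)]
    groups = groups or ["g"] * n
    covs = covs or [{} for _ in range(n)]
    specs = [
        LandmarkConfiguration(ids[i], groups[i], X[i].reshape(k, 3), covariates=covs[i])
        for i in range(n)
    ]
    ds = LandmarkDataset(simple_protocol(k), specs)
    consensus = X.mean(axis=0).reshape(k, 3)
    return AlignedDataset(
        dataset=ds,
        consensus=consensus,
        procrustes_coords=X.reshape(n, k, 3),
        centroid_sizes=np.ones(n),
        rotations=np.tile(np.eye(3), (n, 1, 1)),
        iterations=1,
        converged=True,
        tangent_coords=X,
    )


def _linear_dataset(seed, n=30, k=5, noise=0.0, slope_scale=1.0):
    rng = np.random.default_rng(seed)
    base = rng.standard_normal(3 * k)
    beta = rng.standard_normal(3 * k)
    beta /= np.linalg.norm(beta)
    beta *= slope_scale
    cs = rng.uniform(40, 160, n)
    X = base + np.outer(cs - cs.mean(), beta) + rng.normal(0, noise, (n, 3 * k))
    cov = {f"s{i + 1}": float(cs[i]) for i in range(n)}
    return _aligned_from_tangent(X), cov, beta


class TestShapeRegression:
    def test_noiseless_linear_construction_gives_100pct(self):
        aligned, cov, _ = _linear_dataset(seed=60, noise=0.0, slope_scale=0.01)
        result = shape_regression(aligned, cov)
        assert result.pct_variance_explained == pytest.approx(100.0, abs=1e-8)
        res = np.array([result.residuals[i] for i in result.fit_ids])
        assert np.abs(res).max() < 1e-10

    def test_scores_correlate_perfectly_when_variance_fully_explained(self):
        aligned, cov, _ = _linear_dataset(seed=61, noise=0.0, slope_scale=0.01)
        result = shape_regression(aligned, cov)
        x = np.array([cov[i] for i in result.fit_ids])
        s = np.array([result.regression_scores[i] for i in result.fit_ids])
        r = np.corrcoef(x, s)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_coefficient_vector_recovery(self):
        # known allometric direction injected: cosine similarity >= 0.95
        rng = np.random.default_rng(62)
        n, k = 100, 10
        base = rng.standard_normal(3 * k)
        beta = rng.standard_normal(3 * k)
        beta /= np.linalg.norm(beta)
        cs = rng.uniform(40, 160, n)
        X = base + np.outer(cs - cs.mean(), 0.001 * beta) + rng.normal(0, 0.01, (n, 3 * k))
        aligned = _aligned_from_tangent(X)
        result = shape_regression(aligned, {f"s{i + 1}": float(cs[i]) for i in range(n)})
        unit = result.coefficient_vector / np.linalg.norm(result.coefficient_vector)
        assert abs(unit @ beta) >= 0.95

    def test_sum_of_squares_decomposition(self):
        aligned, cov, _ = _linear_dataset(seed=63, noise=0.5, slope_scale=0.01)
        result = shape_regression(aligned, cov)
        X = result._fit_matrix
        x = result._fit_covariate
        Xc = X - X.mean(axis=0)
        ss_tot = (Xc**2).sum()
        res = np.array([result.residuals[i] for i in result.fit_ids])
        ss_res = (res**2).sum()
        ss_pred = ss_tot * result.pct_variance_explained / 100.0
        assert ss_pred + ss_res == pytest.approx(ss_tot, rel=1e-8)

    def test_residuals_uncorrelated_with_covariate(self):
        aligned, cov, _ = _linear_dataset(seed=64, noise=0.5, slope_scale=0.01)
        result = shape_regression(aligned, cov)
        unit = result.coefficient_vector / np.linalg.norm(result.coefficient_vector)
        x = np.array([cov[i] for i in result.fit_ids])
        proj = np.array([result.residuals[i] @ unit for i in result.fit_ids])
        assert abs(np.cov(proj, x)[0, 1]) < 1e-8

    def test_fossils_never_alter_fit(self):
        aligned, cov, _ = _linear_dataset(seed=65, noise=0.3, slope_scale=0.01)
        result = shape_regression(aligned, cov)
        # append a fossil specimen and refit: coefficients identical
        X = aligned.tangent_coords
        rng = np.random.default_rng(66)
        fossil_row = rng.standard_normal(X.shape[1])
        X2 = np.vstack([X, fossil_row])
        groups = ["g"] * X.shape[0] + ["fossil:F1"]
        aligned2 = _aligned_from_tangent(
            X2, ids=[f"s{i + 1}" for i in range(X.shape[0])] + ["F1"], groups=groups
        )
        cov2 = dict(cov)
        cov2["F1"] = 120.0
        result2 = shape_regression(aligned2, cov2)
        np.testing.assert_allclose(
            result2.coefficient_vector, result.coefficient_vector, atol=1e-12
        )
        assert "F1" in result2.residuals
        assert "F1" not in result2.fit_ids

    def test_zero_covariate_variance_rejected(self):
        aligned, cov, _ = _linear_dataset(seed=67)
        with pytest.raises(ValueError, match="variance"):
            shape_regression(aligned, {i: 1.0 for i in cov})


class TestPermutationPValue:
    def test_constant_shapes_give_p_one(self):
        X = np.tile(np.arange(6.0), (10, 1))
        aligned = _aligned_from_tangent(X)
        cov = {f"s{i + 1}": float(i) for i in range(10)}
        result = shape_regression(aligned, cov)
        assert permutation_pvalue(result, n_perm=99, seed=0) == pytest.approx(1.0)

    def test_perfect_signal_attains_minimum_p(self):
        aligned, cov, _ = _linear_dataset(seed=68, noise=0.0, slope_scale=0.01)
        result = shape_regression(aligned, cov)
        assert permutation_pvalue(result, n_perm=999, seed=1) == pytest.approx(1 / 1000)

    def test_deterministic_given_seed(self):
        aligned, cov, _ = _linear_dataset(seed=69, noise=1.0, slope_scale=0.001)
        result = shape_regression(aligned, cov)
        p1 = permutation_pvalue(result, n_perm=199, seed=7)
        p2 = permutation_pvalue(result, n_perm=199, seed=7)
        assert p1 == p2

    def test_null_rarely_significant(self):
        # covariate permuted against shapes: p > 0.05 in >= 90% of replicates
        n_not_sig = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            X = rng.standard_normal((50, 9))
            cov = {f"s{i + 1}": float(v) for i, v in enumerate(rng.uniform(40, 160, 50))}
            result = shape_regression(_aligned_from_tangent(X), cov)
            if permutation_pvalue(result, n_perm=99, seed=seed) > 0.05 - 1e-12:
                n_not_sig += 1
        assert n_not_sig >= 90

    def test_null_p_values_uniform(self):
        # calibration: KS test across 200 null replicates must not reject
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(5000 + seed)
            X = rng.standard_normal((20, 6))
            cov = {f"s{i + 1}": float(v) for i, v in enumerate(rng.uniform(0, 1, 20))}
            result = shape_regression(_aligned_from_tangent(X), cov)
            ps.append(permutation_pvalue(result, n_perm=99, seed=seed))
        stat, p = stats.kstest(ps, "uniform")
        assert p > 0.01


class TestPredictShape:
    def test_prediction_at_mean_covariate_is_mean_shape(self):
        aligned, cov, _ = _linear_dataset(seed=70, noise=0.2, slope_scale=0.01)
        result = shape_regression(aligned, cov)
        x = result._fit_covariate
        pred = predict_shape_at(result, float(x.mean()))
        mean_shape = result._fit_matrix.mean(axis=0).reshape(-1, 3)
        np.testing.assert_allclose(pred, mean_shape, atol=1e-10)

    def test_predictions_linear_in_covariate(self):
        aligned, cov, _ = _linear_dataset(seed=71, noise=0.2, slope_scale=0.01)
        result = shape_regression(aligned, cov)
        p40, p160 = predict_shape_at(result, 40.0), predict_shape_at(result, 160.0)
        expected = 120.0 * result.coefficient_vector.reshape(-1, 3)
        np.testing.assert_allclose(p160 - p40, expected, atol=1e-10)

    def test_recovers_injected_shape_difference(self):
        rng = np.random.default_rng(72)
        n, k = 80, 8
        base = rng.standard_normal(3 * k)
        beta = rng.standard_normal(3 * k)
        beta /= np.linalg.norm(beta)
        beta *= 0.002
        cs = rng.uniform(40, 160, n)
        X = base + np.outer(cs - cs.mean(), beta) + rng.normal(0, 0.01, (n, 3 * k))
        result = shape_regression(
            _aligned_from_tangent(X), {f"s{i + 1}": float(cs[i]) for i in range(n)}
        )
        diff = predict_shape_at(result, 160.0) - predict_shape_at(result, 40.0)
        np.testing.assert_allclose(diff.ravel(), 120.0 * beta, atol=0.02)


class TestTorsionTable:
    def test_hand_computed_group(self):
        table = torsion_summary_table({"G1": [90.0, 100.0, 110.0]})
        row = table[table.group == "G1"].iloc[0]
        assert row["mean"] == pytest.approx(100.0)
        assert row["N"] == 3
        assert row["SD"] == pytest.approx(10.0)

    def test_overall_n_is_sum_of_group_ns(self):
        rng = np.random.default_rng(73)
        groups = {f"G{i}": rng.normal(120, 10, rng.integers(3, 9)) for i in range(4)}
        table = torsion_summary_table(groups)
        total = table[table.group == "Total"].iloc[0]
        assert total["N"] == sum(len(v) for v in groups.values())

    def test_group_means_recovered_from_synthetic_draws(self):
        rng = np.random.default_rng(74)
        truth = {"A": (116.6, 6.0, 30), "B": (94.2, 5.9, 40), "C": (152.7, 7.1, 35)}
        groups = {g: rng.normal(m, sd, n) for g, (m, sd, n) in truth.items()}
        table = torsion_summary_table(groups)
        for g, (m, sd, n) in truth.items():
            row = table[table.group == g].iloc[0]
            assert abs(row["mean"] - m) < 2 * sd / np.sqrt(n)

    def test_fossils_listed_individually(self):
        table = torsion_summary_table(
            {"G1": [100.0, 110.0, 120.0]}, fossils={"F1": 103.0}
        )
        row = table[table.group == "F1"].iloc[0]
        assert row["N"] == 1
        assert row["mean"] == pytest.approx(103.0)

    def test_empty_group_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped"):
            table = torsion_summary_table({"G1": [100.0, 110.0], "G2": []})
        assert "G2" not in set(table.group)
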