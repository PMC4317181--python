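"""Procrustes machinery: centroid size, pairwise alignment, GPA, tangent space."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shouldergm.landmark_io import LandmarkConfiguration
from shouldergm.superimposition import (
    align_pair,
    centroid_size,
    gpa,
    procrustes_distance,
    procrustes_distance_matrix,
    tangent_project,
)

from conftest import (
    ASYMMETRIC_5PT,
    make_dataset,
    random_config,
    random_rotation,
    rigid_motion,
)
from oracles import brute_centroid_size, grid_search_planar_procrustes


class TestCentroidSize:
    def test_hand_computed_square(self):
        X = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]], dtype=float)
        assert centroid_size(X) == pytest.approx(np.sqrt(8.0), abs=1e-12)

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(deadline=None, max_examples=25)
    def test_homogeneous_in_scale(self, s):
        rng = np.random.default_rng(5)
        X = random_config(rng, 12)
        assert centroid_size(s * X) == pytest.approx(s * centroid_size(X), rel=1e-12)

    def test_rigid_motion_and_mirror_invariant(self):
        rng = np.random.default_rng(6)
        X = random_config(rng, 8)
        moved = rigid_motion(rng, X, scale=False)
        mirrored = X.copy()
        mirrored[:, 2] = -mirrored[:, 2]
        assert centroid_size(moved) == pytest.approx(centroid_size(X), rel=1e-12)
        assert centroid_size(mirrored) == pytest.approx(centroid_size(X), rel=1e-12)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(7)
        X = random_config(rng, 25, scale=10)
        assert centroid_size(X) == pytest.approx(brute_centroid_size(X), abs=1e-12)

    def test_degenerate_configuration_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            centroid_size(np.ones((5, 3)))


class TestAlignPair:
    def test_similarity_transformed_copy_has_zero_distance(self):
        rng = np.random.default_rng(8)
        X = random_config(rng, 10)
        Y = rigid_motion(rng, X)
        aligned, d = align_pair(X, Y)
        assert d < 1e-10
        np.testing.assert_allclose(aligned, X - X.mean(0) + X.mean(0), atol=1e-8)

    def test_mirror_zero_distance_only_with_reflection(self):
        M = ASYMMETRIC_5PT.copy()
        M[:, 0] = -M[:, 0]
        assert procrustes_distance(ASYMMETRIC_5PT, M, allow_reflection=True) < 1e-10
        assert procrustes_distance(ASYMMETRIC_5PT, M, allow_reflection=False) > 0.05

    def test_k_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            align_pair(np.zeros((4, 3)), np.zeros((5, 3)))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_rotation_grid_search_on_planar_configs(self, seed):
        # independent oracle: 0.001-degree rotation scan over the plane
        rng = np.random.default_rng(seed)
        A = np.column_stack([rng.standard_normal((4, 2)), np.zeros(4)])
        B = np.column_stack([rng.standard_normal((4, 2)), np.zeros(4)])
        d = procrustes_distance(A, B, allow_reflection=False)
        assert d == pytest.approx(grid_search_planar_procrustes(A, B), abs=1e-4)

    def test_symmetric(self):
        rng = np.random.default_rng(9)
        A, B = random_config(rng, 6), random_config(rng, 6)
        assert procrustes_distance(A, B) == pytest.approx(
            procrustes_distance(B, A), abs=1e-12
        )

    def test_agrees_with_scipy_procrustes_disparity(self):
        # scipy allows reflections and reports the squared residual
        from scipy.spatial import procrustes as scipy_procrustes

        rng = np.random.default_rng(10)
        A, B = random_config(rng, 9), random_config(rng, 9)
        _, _, disparity = scipy_procrustes(A, B)
        d = procrustes_distance(A, B, allow_reflection=True)
        assert d**2 == pytest.approx(disparity, rel=1e-8)


class TestGPA:
    def test_identical_configs_under_rigid_motions_have_zero_variance(self):
        rng = np.random.default_rng(11)
        X = random_config(rng, 8)
        ds = make_dataset([rigid_motion(rng, X) for _ in range(6)])
        aligned = gpa(ds)
        assert aligned.converged
        spread = aligned.procrustes_coords - aligned.consensus
        assert np.abs(spread).max() < 1e-8

    def test_consensus_unit_size_and_centred(self):
        rng = np.random.default_rng(12)
        ds = make_dataset([random_config(rng, 7) for _ in range(5)])
        aligned = gpa(ds)
        assert np.abs(aligned.consensus.mean(axis=0)).max() < 1e-10
        assert (aligned.consensus**2).sum() == pytest.approx(1.0, abs=1e-10)

    def test_two_configs_equidistant_from_consensus(self):
        rng = np.random.default_rng(13)
        ds = make_dataset([random_config(rng, 6) for _ in range(2)])
        aligned = gpa(ds)
        d1 = np.sqrt(((aligned.procrustes_coords[0] - aligned.consensus) ** 2).sum())
        d2 = np.sqrt(((aligned.procrustes_coords[1] - aligned.consensus) ** 2).sum())
        assert d1 == pytest.approx(d2, rel=1e-6)

    def test_consensus_recovers_simulated_mean(self):
        rng = np.random.default_rng(14)
        true = random_config(rng, 10)
        true = (true - true.mean(0)) / centroid_size(true)
        sigma = 0.01
        n = 20
        ds = make_dataset(
            [rigid_motion(rng, true + rng.normal(0, sigma, true.shape)) for _ in range(n)]
        )
        aligned = gpa(ds)
        _, d = align_pair(true, aligned.consensus)
        # consensus should sit within the sampling error of the true mean
        assert d < 3 * sigma * np.sqrt(true.shape[0] * 3) / np.sqrt(n)

    def test_objective_monotone_on_random_datasets(self):
        # GPA objective (sum of squared distances to the mean) never increases
        for seed in range(50):
            rng = np.random.default_rng(seed)
            k = int(rng.integers(4, 9))
            ds = make_dataset([random_config(rng, k) for _ in range(int(rng.integers(3, 8)))])
            trace = np.array(gpa(ds).objective_trace)
            assert np.all(np.diff(trace) <= 1e-12)

    def test_specimen_order_invariance(self):
        rng = np.random.default_rng(15)
        coords = [random_config(rng, 6) for _ in range(5)]
        a1 = gpa(make_dataset(coords))
        a2 = gpa(make_dataset(coords[::-1]))
        assert align_pair(a1.consensus, a2.consensus)[1] < 1e-8

    def test_rigid_motion_invariance_of_distances(self):
        rng = np.random.default_rng(16)
        coords = [random_config(rng, 7) for _ in range(6)]
        Q = random_rotation(rng)
        t = rng.uniform(-5, 5, 3)
        moved = [c @ Q + t for c in coords]
        a1, a2 = gpa(make_dataset(coords)), gpa(make_dataset(moved))
        d1 = np.sqrt(((a1.procrustes_coords - a1.consensus) ** 2).sum(axis=(1, 2)))
        d2 = np.sqrt(((a2.procrustes_coords - a2.consensus) ** 2).sum(axis=(1, 2)))
        np.testing.assert_allclose(d1, d2, atol=1e-8)

    def test_single_specimen_rejected(self):
        rng = np.random.default_rng(17)
        with pytest.raises(ValueError):
            gpa(make_dataset([random_config(rng, 5)]))


class TestTangentProjection:
    def _aligned(self, seed=18, sigma=0.05, n=8, k=6):
        rng = np.random.default_rng(seed)
        base = random_config(rng, k)
        ds = make_dataset([base + rng.normal(0, sigma, base.shape) for _ in range(n)])
        return gpa(ds)

    def test_consensus_is_fixed_point(self):
        aligned = self._aligned()
        c = aligned.consensus.ravel()
        projected = c + (1.0 - c @ c) * c
        np.testing.assert_allclose(projected, c, atol=1e-12)

    def test_idempotent(self):
        aligned = self._aligned()
        once = aligned.tangent_coords.copy()
        tangent_project(aligned)
        np.testing.assert_allclose(aligned.tangent_coords, once, atol=1e-12)

    def test_correction_shrinks_quadratically_with_noise(self):
        # tangent-minus-Procrustes deviation is O(sigma^2)
        deviations = []
        for sigma in (0.1, 0.01, 0.001):
            aligned = self._aligned(seed=19, sigma=sigma, n=12)
            flat = aligned.procrustes_coords.reshape(12, -1)
            dev = np.abs(aligned.tangent_coords - flat).max()
            deviations.append(dev)
        assert deviations[0] > 50 * deviations[1]
        assert deviations[1] > 50 * deviations[2]


class TestDistanceMatrix:
    def test_identical_shapes_zero_matrix(self):
        rng = np.random.default_rng(20)
        X = random_config(rng, 6)
        D = procrustes_distance_matrix([rigid_motion(rng, X) for _ in range(4)])
        assert np.abs(D).max() < 1e-8

    def test_symmetry_zero_diagonal_and_pairwise_consistency(self):
        rng = np.random.default_rng(21)
        shapes = [random_config(rng, 8) for _ in range(4)]
        D = procrustes_distance_matrix(shapes)
        np.testing.assert_array_equal(D, D.T)
        assert np.all(np.diag(D) == 0)
        for i in range(4):
            for j in range(i + 1, 4):
                assert D[i, j] == pytest.approx(
                    procrustes_distance(shapes[i], shapes[j]), abs=1e-12
                )

    def test_triangle_inequality_on_sampled_triples(self):
        rng = np.random.default_rng(22)
        for _ in range(30):
            a, b, c = (random_config(rng, 6) for _ in range(3))
            dab = procrustes_distance(a, b)
            dbc = procrustes_distance(b, c)
            dac = procrustes_distance(a, c)
            assert dac <= dab + dbc + 1e-12
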