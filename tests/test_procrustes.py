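import numpy as np
import pytest

from trilomorph.errors import DegenerateGeometryError
from trilomorph.procrustes import (align_pair, centroid_size, gpa,
                                   procrustes_distance, tangent_coordinates)


def _standardize(a):
    a = np.asarray(a, dtype=float)
    c = a - a.mean(axis=0)
    return c / np.sqrt((c ** 2).sum())


def _rot(theta):
    return np.array([[np.cos(theta), np.sin(theta)],
                     [-np.sin(theta), np.cos(theta)]])


def grid_min_residual(A, B, step_deg=0.001):
    """Brute-force oracle: minimum residual over an exhaustive rotation grid."""
    A, B = _standardize(A), _standardize(B)
    theta = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    # ||A R(t) - B||^2 = 2 - 2 (a cos t + b sin t) for unit-size shapes
    a = float((A * B).sum())
    b = float((A[:, 0] * B[:, 1] - A[:, 1] * B[:, 0]).sum())
    resid_sq = 2.0 - 2.0 * (a * np.cos(theta) + b * np.sin(theta))
    return float(np.sqrt(max(resid_sq.min(), 0.0)))


class TestCentroidSize:
    def test_unit_square(self):
        # corners at distance sqrt(2)/2 from the center: CS = sqrt(4 * 1/2)
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert centroid_size(square) == pytest.approx(np.sqrt(2.0), abs=1e-12)
        assert centroid_size(2 * square - 1) == pytest.approx(2 * np.sqrt(2.0),
                                                              abs=1e-12)

    def test_doubling_coordinates_doubles_size(self, rng):
        a = rng.normal(size=(7, 2))
        assert centroid_size(2 * a) == pytest.approx(2 * centroid_size(a),
                                                     rel=1e-12)

    def test_matches_direct_formula(self, rng):
        a = rng.normal(size=(7, 2))
        c = a.mean(axis=0)
        expected = np.sqrt(sum((p - c) @ (p - c) for p in a))
        assert centroid_size(a) == pytest.approx(expected, rel=1e-12)

    def test_coincident_landmarks_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            centroid_size(np.ones((7, 2)))


class TestAlignPair:
    def test_recovers_known_rotation(self, rng):
        A = _standardize(rng.normal(size=(7, 2)))
        B = A @ _rot(np.deg2rad(30.0))
        angle, A_rot, resid = align_pair(A, B)
        assert np.degrees(angle) == pytest.approx(30.0, abs=1e-9) or \
            np.degrees(angle) == pytest.approx(-330.0, abs=1e-9)
        assert resid == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(A_rot, B, atol=1e-9)

    def test_identity_alignment(self, rng):
        A = _standardize(rng.normal(size=(7, 2)))
        angle, _, resid = align_pair(A, A)
        assert angle == pytest.approx(0.0, abs=1e-12)
        assert resid == pytest.approx(0.0, abs=1e-12)

    def test_matches_rotation_grid_oracle(self, rng):
        for _ in range(10):
            A = _standardize(rng.normal(size=(7, 2)))
            B = _standardize(rng.normal(size=(7, 2)))
            _, _, resid = align_pair(A, B)
            assert resid == pytest.approx(grid_min_residual(A, B), abs=1e-6)

    def test_no_reflection(self, rng):
        A = _standardize(rng.normal(size=(7, 2)))
        B = A @ np.diag([1.0, -1.0])  # reflected copy
        _, A_rot, resid = align_pair(_standardize(A), _standardize(B))
        # a reflection would give residual 0; rotations cannot reach it
        assert resid > 0.1

    def test_uncentered_input_rejected(self):
        with pytest.raises(ValueError):
            align_pair(np.ones((7, 2)) + np.eye(7, 2), np.eye(7, 2))


class TestProcrustesDistance:
    def test_similarity_invariance(self, rng):
        A = rng.normal(size=(7, 2))
        B = 3.7 * (A @ _rot(1.1)) + np.array([5.0, -2.0])
        assert procrustes_distance(A, B) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self, rng):
        for _ in range(5):
            A, B = rng.normal(size=(7, 2)), rng.normal(size=(7, 2))
            assert procrustes_distance(A, B) == pytest.approx(
                procrustes_distance(B, A), abs=1e-12)

    def test_triangle_inequality(self, rng):
        for _ in range(20):
            A, B, C = (rng.normal(size=(7, 2)) for _ in range(3))
            dab = procrustes_distance(A, B)
            dbc = procrustes_distance(B, C)
            dac = procrustes_distance(A, C)
            assert dac <= dab + dbc + 1e-10

    def test_matches_grid_oracle(self, rng):
        for _ in range(10):
            A, B = rng.normal(size=(7, 2)), rng.normal(size=(7, 2))
            assert procrustes_distance(A, B) == pytest.approx(
                grid_min_residual(A, B), abs=1e-6)


class TestGPA:
    def test_rigid_motion_orbit_collapses(self, rng):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(7, 2))
        configs = [rng.uniform(0.5, 2) * (base @ _rot(rng.uniform(-np.pi, np.pi)))
                   + rng.uniform(-5, 5, 2) for _ in range(12)]
        fit = gpa(configs)
        for a in fit.aligned:
            np.testing.assert_allclose(a, fit.aligned[0], atol=1e-8)
        assert procrustes_distance(fit.mean_shape, base) == pytest.approx(0.0,
                                                                          abs=1e-8)

    def test_two_shape_mean_is_midway(self, rng):
        A, B = rng.normal(size=(7, 2)), rng.normal(size=(7, 2))
        fit = gpa([A, B])
        da = procrustes_distance(fit.mean_shape, A)
        db = procrustes_distance(fit.mean_shape, B)
        assert da == pytest.approx(db, abs=1e-9)

    def test_recovers_known_mean_shape(self):
        rng = np.random.default_rng(13)
        mean = rng.normal(size=(7, 2))
        mean = (mean - mean.mean(0)) / np.sqrt(((mean - mean.mean(0)) ** 2).sum())
        sigma = 0.01
        configs = [mean + rng.normal(0, sigma, (7, 2)) for _ in range(30)]
        fit = gpa(configs)
        # consensus error scale is sigma * sqrt(2k - 4) / sqrt(n)
        assert procrustes_distance(fit.mean_shape, mean) < 2 * sigma * np.sqrt(10 / 30)

    def test_invariant_to_input_pretransformations(self, rng):
        configs = [rng.normal(size=(7, 2)) for _ in range(8)]
        fit1 = gpa(configs)
        moved = [2.5 * (c @ _rot(0.7)) + np.array([1.0, -3.0]) for c in configs]
        fit2 = gpa(moved)
        for a, b in zip(fit1.aligned, fit2.aligned):
            np.testing.assert_allclose(a, b, atol=1e-8)

    def test_objective_nonincreasing(self, rng):
        configs = [rng.normal(size=(7, 2)) for _ in range(15)]
        fit = gpa(configs)
        ss = np.array(fit.ss_history)
        assert np.all(np.diff(ss) <= 1e-12)

    def test_aligned_shapes_centered_unit_mean(self, rng):
        fit = gpa([rng.normal(size=(7, 2)) for _ in range(6)])
        for a in fit.aligned:
            np.testing.assert_allclose(a.mean(axis=0), 0, atol=1e-9)
        assert np.sqrt((fit.mean_shape ** 2).sum()) == pytest.approx(1.0,
                                                                    abs=1e-9)

    def test_single_config_rejected(self, rng):
        with pytest.raises(ValueError):
            gpa([rng.normal(size=(7, 2))])


class TestTangentCoordinates:
    def test_mean_projects_to_zero(self, rng):
        configs = [rng.normal(size=(7, 2)) for _ in range(10)]
        fit = gpa(configs)
        m = fit.mean_shape.ravel()
        t = m - np.outer(np.atleast_1d(m @ m), m).ravel()
        np.testing.assert_allclose(t, 0, atol=1e-12)

    def test_rank_at_most_2k_minus_4(self, rng):
        fit = gpa([rng.normal(size=(7, 2)) for _ in range(30)])
        T = tangent_coordinates(fit)
        rank = np.linalg.matrix_rank(T, tol=1e-9)
        assert rank <= 10

    def test_local_isometry_for_small_dispersion(self):
        rng = np.random.default_rng(99)
        mean = _standardize(rng.normal(size=(7, 2)))
        configs = [mean + rng.normal(0, 0.001, (7, 2)) for _ in range(12)]
        fit = gpa(configs)
        T = tangent_coordinates(fit)
        for i in range(0, 10, 3):
            for j in range(i + 1, 12, 4):
                d_t = np.linalg.norm(T[i] - T[j])
                d_p = procrustes_distance(fit.aligned[i], fit.aligned[j])
                assert d_t == pytest.approx(d_p, rel=1e-3)
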