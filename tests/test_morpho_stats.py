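from itertools import combinations

import numpy as np
import pytest

from trilomorph.errors import SampleSizeError
from trilomorph.morpho_stats import (cva_analysis, goodall_f, permutation_null,
                                     procrustes_anova, shape_pca)
from trilomorph.procrustes import gpa, tangent_coordinates
from trilomorph.simulate import PopulationSpec, simulate_population


def two_group_fit(sep=0.0, sd=0.01, n=12, seed=0, mean=None):
    rng = np.random.default_rng(seed)
    if mean is None:
        mean = rng.normal(size=(7, 2))
    mean_b = mean + np.concatenate([[sep], np.zeros(13)]).reshape(7, 2)
    a = simulate_population(PopulationSpec(mean, dispersion=sd, n=n, label="A",
                                           seed=seed + 1))
    b = simulate_population(PopulationSpec(mean_b, dispersion=sd, n=n, label="B",
                                           seed=seed + 2))
    configs = a + b
    return gpa(configs), [c.population for c in configs]


class TestShapePca:
    def test_rank_one_data_gives_single_component(self, rng):
        # a one-parameter family along a direction orthogonal to translation,
        # scale and rotation stays a straight line in tangent space
        base = rng.normal(size=(7, 2))
        base -= base.mean(axis=0)
        base /= np.sqrt((base ** 2).sum())
        J = np.array([[0.0, 1.0], [-1.0, 0.0]])
        span = np.column_stack([np.tile([1.0, 0.0], 7), np.tile([0.0, 1.0], 7),
                                base.ravel(), (base @ J).ravel()])
        d = rng.normal(size=14)
        d -= span @ np.linalg.lstsq(span, d, rcond=None)[0]
        d = 0.05 * d.reshape(7, 2) / np.linalg.norm(d)
        configs = [base + t * d for t in np.linspace(-1, 1, 9)]
        pca = shape_pca(gpa(configs))
        assert pca.pct_variance[0] == pytest.approx(100.0, abs=1e-6)

    def test_pct_variance_sums_to_100(self, random_configs):
        pca = shape_pca(gpa(random_configs))
        assert pca.pct_variance.sum() == pytest.approx(100.0, abs=1e-6)

    def test_components_orthonormal_and_bounded_rank(self, random_configs):
        pca = shape_pca(gpa(random_configs))
        assert pca.components.shape[0] <= 10
        gram = pca.components @ pca.components.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-9)

    def test_matches_bruteforce_eigendecomposition(self, random_configs):
        fit = gpa(random_configs)
        pca = shape_pca(fit)
        T = tangent_coordinates(fit)
        Tc = T - T.mean(axis=0)
        C = (Tc.T @ Tc) / (len(Tc) - 1)
        evals = np.sort(np.linalg.eigvalsh(C))[::-1]
        np.testing.assert_allclose(pca.eigenvalues, evals[:len(pca.eigenvalues)],
                                   atol=1e-8)
        # scores reproduce Tc in the retained basis
        np.testing.assert_allclose(pca.scores @ pca.components, Tc, atol=1e-8)

    def test_scores_invariant_to_specimen_order(self, random_configs):
        pca1 = shape_pca(gpa(random_configs))
        rev = list(reversed(random_configs))
        pca2 = shape_pca(gpa(rev))
        # same eigenvalues; scores agree up to component sign
        np.testing.assert_allclose(pca1.eigenvalues, pca2.eigenvalues, rtol=1e-6)
        for j in range(3):
            s1 = pca1.scores[:, j]
            s2 = pca2.scores[::-1, j]
            assert (np.allclose(s1, s2, atol=1e-6)
                    or np.allclose(s1, -s2, atol=1e-6))

    def test_too_few_specimens_rejected(self, rng):
        fit = gpa([rng.normal(size=(7, 2)) for _ in range(2)])
        with pytest.raises(SampleSizeError):
            shape_pca(fit)


class TestGoodallF:
    def test_identical_shape_distributions_give_zero_f(self, rng):
        base = rng.normal(size=(7, 2))
        group_a = [base + rng.normal(0, 0.01, (7, 2)) for _ in range(6)]
        # group B: rigid-motion copies of group A's specimens (same shapes)
        theta = 0.8
        R = np.array([[np.cos(theta), np.sin(theta)],
                      [-np.sin(theta), np.cos(theta)]])
        group_b = [3.0 * (a @ R) + 7.0 for a in group_a]
        from trilomorph.landmarking import LandmarkConfiguration
        configs = ([LandmarkConfiguration(a, population="A") for a in group_a]
                   + [LandmarkConfiguration(b, population="B") for b in group_b])
        fit = gpa(configs)
        res = goodall_f(fit, "A", "B", n_resamples=99, seed=1)
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_degrees_of_freedom(self):
        fit, labels = two_group_fit(n=10, seed=3)
        res = goodall_f(fit, "A", "B", n_resamples=49, seed=0, labels=labels)
        assert res.df_num == 10           # 2k - 4 with k = 7
        assert res.df_den == 18 * 10      # (n_a + n_b - 2)(2k - 4)

    def test_two_group_anova_equals_pairwise(self):
        fit, labels = two_group_fit(sep=0.03, n=9, seed=7)
        pair = goodall_f(fit, "A", "B", n_resamples=9, seed=0, labels=labels)
        _, omni = procrustes_anova(fit, labels, n_resamples=9, seed=0)
        assert omni.F == pytest.approx(pair.F, abs=1e-10)
        assert omni.df_num == pair.df_num and omni.df_den == pair.df_den

    def test_small_group_rejected(self):
        fit, labels = two_group_fit(n=4, seed=5)
        labels = ["A"] * 7 + ["B"]
        with pytest.raises(SampleSizeError):
            goodall_f(fit, "A", "B", labels=labels)

    def test_invariant_to_global_pretransformation(self, rng):
        rng = np.random.default_rng(21)
        configs_raw = [rng.normal(size=(7, 2)) for _ in range(16)]
        labels = ["A"] * 8 + ["B"] * 8
        from trilomorph.landmarking import LandmarkConfiguration

        def result(transform):
            cfgs = [LandmarkConfiguration(transform(c), population=l)
                    for c, l in zip(configs_raw, labels)]
            return goodall_f(gpa(cfgs), "A", "B", n_resamples=19, seed=0)

        theta = 1.234
        R = np.array([[np.cos(theta), np.sin(theta)],
                      [-np.sin(theta), np.cos(theta)]])
        r1 = result(lambda c: c)
        r2 = result(lambda c: 5.0 * (c @ R) + np.array([2.0, -1.0]))
        assert r1.F == pytest.approx(r2.F, rel=1e-8)

    def test_bootstrap_resampling_available(self):
        fit, labels = two_group_fit(sep=0.05, n=8, seed=11)
        res = goodall_f(fit, "A", "B", n_resamples=49, seed=2, labels=labels,
                        resampling="bootstrap")
        assert 0.0 < res.p_resample <= 1.0


class TestProcrustesAnova:
    def test_three_group_degrees_of_freedom(self, rng):
        # k = 7, g = 3: size df 2, shape df 20
        mean = rng.normal(size=(7, 2))
        configs = sum((simulate_population(
            PopulationSpec(mean, dispersion=0.01, n=6, label=l, seed=i))
            for i, l in enumerate(["x", "y", "z"])), [])
        fit = gpa(configs)
        size_r, shape_r = procrustes_anova(fit, [c.population for c in configs],
                                           n_resamples=19, seed=0)
        assert size_r.df_num == 2
        assert shape_r.df_num == 20

    def test_identical_groups_give_zero_f(self, rng):
        base = [rng.normal(size=(7, 2)) for _ in range(5)]
        from trilomorph.landmarking import LandmarkConfiguration
        configs = [LandmarkConfiguration(b, population=l)
                   for l in ("p", "q", "r") for b in base]
        fit = gpa(configs)
        size_r, shape_r = procrustes_anova(fit, [c.population for c in configs],
                                           n_resamples=19, seed=0)
        assert size_r.F == pytest.approx(0.0, abs=1e-9)
        assert shape_r.F == pytest.approx(0.0, abs=1e-9)

    def test_single_group_rejected(self, rng):
        fit, _ = two_group_fit(n=5, seed=1)
        with pytest.raises(SampleSizeError):
            procrustes_anova(fit, ["only"] * 10, n_resamples=9)


class TestPermutationNull:
    def test_label_independent_statistic_gives_p_one(self, rng):
        res = permutation_null(lambda l: 42.0, ["a"] * 5 + ["b"] * 5, 50, 1)
        assert res.p == 1.0 and res.degenerate

    def test_same_seed_reproducible(self, rng):
        data = rng.normal(size=10)
        labels = np.array(["a"] * 5 + ["b"] * 5)

        def stat(l):
            return abs(data[l == "a"].mean() - data[l == "b"].mean())

        r1 = permutation_null(stat, labels, 200, seed=7)
        r2 = permutation_null(stat, labels, 200, seed=7)
        np.testing.assert_array_equal(r1.null, r2.null)
        assert r1.p == r2.p

    def test_matches_exhaustive_enumeration_on_tiny_sample(self):
        # 3 vs 3: all 20 label splits enumerable exactly
        data = np.array([0.1, 0.5, 0.9, 1.2, 1.7, 2.5])
        labels = np.array(["a", "a", "a", "b", "b", "b"])

        def stat(l):
            return data[l == "b"].mean() - data[l == "a"].mean()

        t_obs = stat(labels)
        exhaustive = []
        for idx in combinations(range(6), 3):
            l = np.array(["b" if i in idx else "a" for i in range(6)])
            exhaustive.append(stat(l))
        p_exact = np.mean(np.array(exhaustive) >= t_obs - 1e-12)
        res = permutation_null(stat, labels, 20000, seed=3)
        assert res.p == pytest.approx(p_exact, abs=0.01)


class TestCvaAnalysis:
    def test_three_groups_give_two_axes(self, rng):
        mean = rng.normal(size=(7, 2))
        configs = sum((simulate_population(
            PopulationSpec(mean, dispersion=0.02, n=8, label=l, seed=i))
            for i, l in enumerate(["g1", "g2", "g3"])), [])
        cva = cva_analysis(gpa(configs), [c.population for c in configs],
                           n_permutations=19, seed=0)
        assert cva.cv_scores.shape == (24, 2)

    def test_distance_matrices_symmetric_zero_diagonal(self, rng):
        fit, labels = two_group_fit(sep=0.02, n=8, seed=9)
        cva = cva_analysis(fit, labels, n_permutations=19, seed=0)
        for mat in (cva.mahalanobis, cva.procrustes_dist):
            np.testing.assert_allclose(mat, mat.T)
            np.testing.assert_allclose(np.diag(mat), 0.0)
            assert np.all(mat >= 0)

    def test_mahalanobis_matches_bruteforce_formula(self):
        fit, labels = two_group_fit(sep=0.03, n=10, seed=15)
        cva = cva_analysis(fit, labels, n_permutations=9, seed=0)
        from trilomorph.morpho_stats import _pooled_within, _reduce_rank
        T = tangent_coordinates(fit)
        lab = np.asarray(labels)
        Y = _reduce_rank(T, min(fit.shape_dim, fit.n - 2))
        W, means = _pooled_within(Y, lab, np.array(["A", "B"]))
        d = means[0] - means[1]
        expected = np.sqrt(d @ np.linalg.inv(W) @ d)
        assert cva.mahalanobis[0, 1] == pytest.approx(expected, abs=1e-8)

    def test_mahalanobis_invariant_to_linear_reparameterization(self):
        # the distance depends only on the metric, not on the basis
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(30, 5))
        lab = np.array(["A"] * 15 + ["B"] * 15)
        Y[lab == "B"] += 0.5
        from trilomorph.morpho_stats import _pooled_within
        A = rng.normal(size=(5, 5)) + 3 * np.eye(5)  # nonsingular

        def mahal(Z):
            W, means = _pooled_within(Z, lab, np.array(["A", "B"]))
            d = means[0] - means[1]
            return np.sqrt(d @ np.linalg.inv(W) @ d)

        assert mahal(Y @ A) == pytest.approx(mahal(Y), rel=1e-8)

    def test_separated_groups_detected(self):
        fit, labels = two_group_fit(sep=0.05, sd=0.01, n=20, seed=23)
        cva = cva_analysis(fit, labels, n_permutations=999, seed=0)
        assert cva.p_mahalanobis[0, 1] <= 0.001
        assert cva.p_procrustes[0, 1] <= 0.001

    def test_single_group_rejected(self):
        fit, _ = two_group_fit(n=5, seed=2)
        with pytest.raises(SampleSizeError):
            cva_analysis(fit, ["g"] * 10, n_permutations=9)
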