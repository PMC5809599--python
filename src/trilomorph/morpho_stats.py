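"""Shape statistics on Procrustes-aligned configurations.

Implements the standard battery for comparing landmark-shape samples between
groups: covariance-matrix PCA of tangent coordinates, Goodall's F-test
(pairwise and as a multi-group Procrustes ANOVA, with permutation p-values),
and canonical variates analysis with Mahalanobis and Procrustes distances
between group means, each with permutation tests.

Goodall's F partitions squared Procrustes distance — here computed with
Euclidean norms on the aligned Procrustes coordinates, the usual linearized
treatment, which makes the two-group ANOVA exactly equal to the pairwise
test. With k landmarks in 2-D each group contrast carries 2k - 4 shape
degrees of freedom. Because landmark dispersion is rarely isotropic, the
parametric p-value is complemented by a label-permutation p-value (the
default resampling scheme; bootstrap over the pooled sample is available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

from .errors import SampleSizeError
from .procrustes import ProcrustesFit, procrustes_distance, tangent_coordinates

DEFAULT_N_PERMUTATIONS = 10_000
RANK_TOL = 1e-12


@dataclass
class PCAResult:
    """Covariance-matrix PCA of tangent coordinates."""

    eigenvalues: np.ndarray    # descending, nonzero components only
    pct_variance: np.ndarray   # percentages, sum to 100
    scores: np.ndarray         # (n, m), centered
    components: np.ndarray     # (m, 2k), orthonormal rows


@dataclass
class GoodallResult:
    """Goodall's F between shape samples (or a one-way size ANOVA)."""

    F: float
    df_num: int
    df_den: int
    p_param: float
    p_resample: float
    n_resamples: int
    infinite_f: bool = False


@dataclass
class CVAResult:
    """Canonical variates analysis with between-group distance tests."""

    cv_scores: np.ndarray        # (n, n_axes)
    cv_axes: np.ndarray          # (r, n_axes) in reduced-PC space
    eigenvalues: np.ndarray      # canonical roots, descending
    groups: list[str]
    mahalanobis: np.ndarray      # (g, g)
    procrustes_dist: np.ndarray  # (g, g)
    p_mahalanobis: np.ndarray    # (g, g)
    p_procrustes: np.ndarray     # (g, g)
    n_permutations: int


@dataclass
class PermutationNull:
    """Null sample and p-value from a label-permutation test."""

    observed: float
    null: np.ndarray
    p: float
    degenerate: bool  # statistic did not vary over permutations


def permutation_null(statistic_fn: Callable[[np.ndarray], float],
                     labels: Sequence, n_permutations: int,
                     seed: int | np.random.Generator) -> PermutationNull:
    """Generic label-permutation test.

    ``statistic_fn`` maps a label array to a scalar; labels are permuted
    uniformly without replacement. p = (1 + #{T* >= T_obs}) / (1 + n), the
    add-one convention that never returns an exact zero.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels = np.asarray(labels)
    t_obs = float(statistic_fn(labels))
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = statistic_fn(rng.permutation(labels))
    p = (1.0 + np.sum(null >= t_obs - 1e-300)) / (1.0 + n_permutations)
    degenerate = bool(np.allclose(null, t_obs))
    if degenerate:
        p = 1.0
    return PermutationNull(observed=t_obs, null=null, p=float(p), degenerate=degenerate)


def _group_coords(fit: ProcrustesFit, labels: Sequence[str] | None) -> tuple[np.ndarray, np.ndarray]:
    X = fit.aligned.reshape(fit.n, -1)
    lab = np.asarray(fit.labels if labels is None else list(labels))
    if len(lab) != fit.n:
        raise ValueError("labels must align with the fitted configurations")
    return X, lab


def shape_pca(fit: ProcrustesFit) -> PCAResult:
    """PCA of the tangent-coordinate covariance matrix.

    Components with eigenvalues below ``RANK_TOL`` x the leading eigenvalue
    are dropped (the tangent data are rank-deficient by construction: at most
    2k - 4 nonzero directions). Percent variance is over the retained
    components and sums to 100.
    """
    if fit.n < 3:
        raise SampleSizeError("PCA needs at least 3 specimens")
    T = tangent_coordinates(fit)
    Tc = T - T.mean(axis=0)
    C = np.cov(Tc, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    keep = evals > RANK_TOL * max(evals[0], 1e-300)
    keep &= np.arange(len(evals)) < min(fit.shape_dim, fit.n - 1)
    evals, evecs = evals[keep], evecs[:, keep]
    scores = Tc @ evecs
    pct = 100.0 * evals / evals.sum()
    return PCAResult(eigenvalues=evals, pct_variance=pct, scores=scores,
                     components=evecs.T)


def _goodall_f_stat(X: np.ndarray, lab: np.ndarray, groups: np.ndarray,
                    q: int) -> tuple[float, int, int, float]:
    """Omnibus Goodall partition; returns (F, df_num, df_den, ssw)."""
    n = len(X)
    g = len(groups)
    grand = X.mean(axis=0)
    ssb = ssw = 0.0
    for gr in groups:
        sel = lab == gr
        m = X[sel].mean(axis=0)
        ssb += sel.sum() * float(((m - grand) ** 2).sum())
        ssw += float(((X[sel] - m) ** 2).sum())
    df_num = (g - 1) * q
    df_den = (n - g) * q
    if ssw <= 0:
        return np.inf, df_num, df_den, ssw
    return (ssb / df_num) / (ssw / df_den), df_num, df_den, ssw


def goodall_f(fit: ProcrustesFit, group_a: str, group_b: str,
              n_resamples: int = DEFAULT_N_PERMUTATIONS, seed: int = 0,
              labels: Sequence[str] | None = None,
              resampling: str = "permutation") -> GoodallResult:
    """Pairwise Goodall's F-test between two labeled groups.

    F = [n_a n_b / (n_a + n_b) * d^2(mean_a, mean_b) / (2k-4)] /
        [sum_i d^2(x_i, own mean) / ((n_a + n_b - 2)(2k-4))]
    with d Euclidean on aligned Procrustes coordinates. The parametric
    p-value uses the F distribution with those df; the resampled p-value
    randomly reassigns specimens to the two groups.
    """
    X, lab = _group_coords(fit, labels)
    sel = (lab == group_a) | (lab == group_b)
    if (lab == group_a).sum() < 2 or (lab == group_b).sum() < 2:
        raise SampleSizeError("both groups need at least 2 specimens")
    Xp, labp = X[sel], lab[sel]
    q = fit.shape_dim
    groups = np.array([group_a, group_b])

    def stat(l: np.ndarray) -> float:
        return _goodall_f_stat(Xp, l, groups, q)[0]

    F, df_num, df_den, ssw = _goodall_f_stat(Xp, labp, groups, q)
    infinite = not np.isfinite(F)
    p_param = 0.0 if infinite else float(sps.f.sf(F, df_num, df_den))
    rng = np.random.default_rng(seed)
    if resampling == "permutation":
        perm = permutation_null(stat, labp, n_resamples, rng)
        p_res = perm.p
    elif resampling == "bootstrap":
        # resample specimens with replacement from the pooled sample,
        # keeping the group sizes; compare F* to the observed F
        null = np.empty(n_resamples)
        for i in range(n_resamples):
            idx = rng.integers(0, len(Xp), len(Xp))
            null[i] = _goodall_f_stat(Xp[idx], labp, groups, q)[0]
        p_res = float((1.0 + np.sum(null >= F)) / (1.0 + n_resamples))
    else:
        raise ValueError("resampling must be 'permutation' or 'bootstrap'")
    return GoodallResult(F=float(F), df_num=df_num, df_den=df_den,
                         p_param=p_param, p_resample=p_res,
                         n_resamples=n_resamples, infinite_f=infinite)


def procrustes_anova(fit: ProcrustesFit, labels: Sequence[str] | None = None,
                     n_resamples: int = DEFAULT_N_PERMUTATIONS,
                     seed: int = 0) -> tuple[GoodallResult, GoodallResult]:
    """Multi-group test: one-way ANOVA on centroid size + Goodall shape ANOVA.

    Size: df_num = g - 1, df_den = n - g. Shape: df_num = (g-1)(2k-4),
    df_den = (n-g)(2k-4). With two groups the shape F equals the pairwise
    Goodall F exactly.
    """
    X, lab = _group_coords(fit, labels)
    groups = np.array(list(dict.fromkeys(lab)))
    if len(groups) < 2:
        raise SampleSizeError("need at least 2 groups")
    for gr in groups:
        if (lab == gr).sum() < 2:
            raise SampleSizeError(f"group {gr!r} has fewer than 2 specimens")
    rng = np.random.default_rng(seed)

    # --- centroid size: classic one-way ANOVA
    sizes = fit.centroid_sizes
    g, n = len(groups), len(sizes)

    def size_stat(l: np.ndarray) -> float:
        grand = sizes.mean()
        ssb = sum((l == gr).sum() * (sizes[l == gr].mean() - grand) ** 2 for gr in groups)
        ssw = sum(((sizes[l == gr] - sizes[l == gr].mean()) ** 2).sum() for gr in groups)
        if ssw <= 0:
            return np.inf
        return (ssb / (g - 1)) / (ssw / (n - g))

    F_size = size_stat(lab)
    p_size = 0.0 if not np.isfinite(F_size) else float(sps.f.sf(F_size, g - 1, n - g))
    perm_size = permutation_null(size_stat, lab, n_resamples, rng)
    size_res = GoodallResult(F=float(F_size), df_num=g - 1, df_den=n - g,
                             p_param=p_size, p_resample=perm_size.p,
                             n_resamples=n_resamples,
                             infinite_f=not np.isfinite(F_size))

    # --- shape: omnibus Goodall partition
    q = fit.shape_dim

    def shape_stat(l: np.ndarray) -> float:
        return _goodall_f_stat(X, l, groups, q)[0]

    F_shape, df_num, df_den, _ = _goodall_f_stat(X, lab, groups, q)
    infinite = not np.isfinite(F_shape)
    p_shape = 0.0 if infinite else float(sps.f.sf(F_shape, df_num, df_den))
    perm_shape = permutation_null(shape_stat, lab, n_resamples, rng)
    shape_res = GoodallResult(F=float(F_shape), df_num=df_num, df_den=df_den,
                              p_param=p_shape, p_resample=perm_shape.p,
                              n_resamples=n_resamples, infinite_f=infinite)
    return size_res, shape_res


def _reduce_rank(T: np.ndarray, max_dim: int) -> np.ndarray:
    """Project tangent coordinates onto PCs with non-negligible eigenvalues."""
    Tc = T - T.mean(axis=0)
    C = np.cov(Tc, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
    keep = evals > RANK_TOL * max(evals[0], 1e-300)
    keep &= np.arange(len(evals)) < max_dim
    return Tc @ evecs[:, keep]


def _pooled_within(Y: np.ndarray, lab: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    means = np.stack([Y[lab == gr].mean(axis=0) for gr in groups])
    W = np.zeros((Y.shape[1], Y.shape[1]))
    for gi, gr in enumerate(groups):
        d = Y[lab == gr] - means[gi]
        W += d.T @ d
    W /= (len(Y) - len(groups))
    return W, means


def cva_analysis(fit: ProcrustesFit, labels: Sequence[str] | None = None,
                 n_permutations: int = DEFAULT_N_PERMUTATIONS,
                 seed: int = 0) -> CVAResult:
    """Canonical variates analysis of tangent coordinates.

    Tangent data are first projected onto principal components carrying
    non-negligible variance (rank repair; at most min(2k-4, n-g) kept so the
    pooled within-group covariance is invertible). Canonical axes solve the
    between- vs within-group generalized eigenproblem; at most g - 1 axes.
    Pairwise Mahalanobis distances use the pooled within-group covariance;
    pairwise Procrustes distances are between group mean shapes. Both get
    permutation p-values by reshuffling the two groups' labels.
    """
    T = tangent_coordinates(fit)
    _, lab = _group_coords(fit, labels)
    groups = np.array(list(dict.fromkeys(lab)))
    g = len(groups)
    if g < 2:
        raise SampleSizeError("CVA needs at least 2 groups")
    counts = {gr: int((lab == gr).sum()) for gr in groups}
    max_dim = min(fit.shape_dim, fit.n - g)
    if any(c < 3 for c in counts.values()):
        warnings.warn("a group has fewer than 3 specimens; forcing rank reduction")
        max_dim = min(max_dim, fit.n - g - 1)
    Y = _reduce_rank(T, max_dim)
    r = Y.shape[1]
    W, means = _pooled_within(Y, lab, groups)
    grand = Y.mean(axis=0)
    B = np.zeros_like(W)
    for gi, gr in enumerate(groups):
        d = (means[gi] - grand)[:, None]
        B += counts[gr] * (d @ d.T)
    B /= max(g - 1, 1)
    # canonical axes via symmetric whitening: W^{-1/2} B W^{-1/2}
    wvals, wvecs = np.linalg.eigh(W)
    wvals = np.clip(wvals, 1e-300, None)
    W_isqrt = wvecs @ np.diag(wvals ** -0.5) @ wvecs.T
    K = W_isqrt @ B @ W_isqrt
    kvals, kvecs = np.linalg.eigh(K)
    order = np.argsort(kvals)[::-1]
    n_axes = min(g - 1, r)
    kvals, kvecs = kvals[order][:n_axes], kvecs[:, order][:, :n_axes]
    axes = W_isqrt @ kvecs
    cv_scores = (Y - grand) @ axes

    def _mahal(mi: np.ndarray, mj: np.ndarray, Winv: np.ndarray) -> float:
        d = mi - mj
        return float(np.sqrt(d @ Winv @ d))

    mean_shapes = {gr: fit.aligned[lab == gr].mean(axis=0) for gr in groups}
    D_m = np.zeros((g, g))
    D_p = np.zeros((g, g))
    P_m = np.zeros((g, g))
    P_p = np.zeros((g, g))
    rng = np.random.default_rng(seed)
    for i in range(g):
        for j in range(i + 1, g):
            # pairwise distances use the pooled covariance of the pair, the
            # same quantity the permutation null recomputes
            sel = (lab == groups[i]) | (lab == groups[j])
            Wij, mij = _pooled_within(Y[sel], lab[sel],
                                      np.array([groups[i], groups[j]]))
            D_m[i, j] = D_m[j, i] = _mahal(mij[0], mij[1], np.linalg.inv(Wij))
            D_p[i, j] = D_p[j, i] = procrustes_distance(mean_shapes[groups[i]],
                                                        mean_shapes[groups[j]])
            Yij, labij = Y[sel], lab[sel]
            Aij = fit.aligned[sel]
            ni = counts[groups[i]]
            null_m = np.empty(n_permutations)
            null_p = np.empty(n_permutations)
            for t in range(n_permutations):
                perm = rng.permutation(len(labij))
                ia, ib = perm[:ni], perm[ni:]
                Wp, mp = _pooled_within(Yij, np.isin(np.arange(len(labij)), ia),
                                        np.array([True, False]))
                null_m[t] = _mahal(mp[0], mp[1], np.linalg.inv(Wp))
                null_p[t] = procrustes_distance(Aij[ia].mean(axis=0),
                                                Aij[ib].mean(axis=0))
            P_m[i, j] = P_m[j, i] = (1 + np.sum(null_m >= D_m[i, j])) / (1 + n_permutations)
            P_p[i, j] = P_p[j, i] = (1 + np.sum(null_p >= D_p[i, j])) / (1 + n_permutations)
    return CVAResult(cv_scores=cv_scores, cv_axes=axes, eigenvalues=kvals,
                     groups=list(groups), mahalanobis=D_m, procrustes_dist=D_p,
                     p_mahalanobis=P_m, p_procrustes=P_p,
                     n_permutations=n_permutations)


def bonferroni(p: float, n_tests: int) -> float:
    """Bonferroni-adjusted p-value (min(1, n p)); reported alongside raw p."""
    return float(min(1.0, p * n_tests))
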