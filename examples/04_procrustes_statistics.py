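"""The geometric-morphometrics battery on simulated landmark populations.

Two populations share a mean shape except for a planted offset; the script
runs the full Procrustes fit (GPA), covariance PCA, Goodall's F with a
permutation p-value, and CVA with Mahalanobis/Procrustes distances — the
statistics used to compare glabellar profile shapes between localities.
"""

import numpy as np

from trilomorph import (PopulationSpec, cva_analysis, goodall_f, gpa,
                        procrustes_anova, shape_pca, simulate_population)

rng = np.random.default_rng(11)
mean_a = rng.normal(size=(7, 2))
shift = rng.normal(size=(7, 2))
shift *= 0.03 / np.linalg.norm(shift)       # planted mean-shape difference
pop_a = simulate_population(PopulationSpec(mean_a, 0.01, n=18, label="A", seed=1))
pop_b = simulate_population(PopulationSpec(mean_a + shift, 0.01, n=16, label="B", seed=2))

configs = pop_a + pop_b
labels = [c.population for c in configs]
fit = gpa(configs)
print(f"GPA converged in {fit.iterations} iterations over {fit.n} specimens")

pca = shape_pca(fit)
print(f"PC1/PC2/PC3 variance: {pca.pct_variance[0]:.1f}% / "
      f"{pca.pct_variance[1]:.1f}% / {pca.pct_variance[2]:.1f}%")

size_r, shape_r = procrustes_anova(fit, labels, n_resamples=999, seed=3)
print(f"Centroid size: F = {size_r.F:.2f}, df = {size_r.df_num}, "
      f"p(perm) = {size_r.p_resample:.3f}")
print(f"Shape:         F = {shape_r.F:.2f}, df = {shape_r.df_num}, "
      f"p(perm) = {shape_r.p_resample:.4f}")

g = goodall_f(fit, "A", "B", n_resamples=999, seed=4, labels=labels)
print(f"Goodall A vs B: F = {g.F:.2f}, p(perm) = {g.p_resample:.4f}")

cva = cva_analysis(fit, labels, n_permutations=999, seed=5)
print(f"Mahalanobis D(A,B) = {cva.mahalanobis[0, 1]:.3f}, "
      f"p(perm) = {cva.p_mahalanobis[0, 1]:.4f}")
print(f"Procrustes  d(A,B) = {cva.procrustes_dist[0, 1]:.4f}, "
      f"p(perm) = {cva.p_procrustes[0, 1]:.4f}")
print("\nA small planted shape offset (0.03 in unit-size shape space) is")
print("already highly significant at these sample sizes; F near 1 and large")
print("p-values would instead indicate a single shared population.")
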