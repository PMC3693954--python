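"""Ecotype clustering, ordination, SDMs and niche divergence tests.

Simulates an environmental raster with three displaced Gaussian niches,
clusters the occurrences (BIC-selected Gaussian mixture), ordains them
by correlation PCA, fits maximum-entropy-style SDMs, and runs the niche
overlap / identity and background-divergence tests for one ecotype pair.
"""

import numpy as np

from haploniche import (
    ecotype_cluster, pca_ordination, between_class_inertia, dfa,
    fit_sdm, evaluate_auc, niche_overlap, identity_test, background_test,
)
from haploniche.simulate import NicheSimSpec, simulate_niche_world

raster, occ = simulate_niche_world(NicheSimSpec(seed=2))
truth = occ.data["ecotype"].to_numpy()

cl = ecotype_cluster(occ, k_range=range(1, 6), seed=0)
print(f"BIC selects k = {cl.n_clusters} ecotypes "
      f"(BIC by k: {[round(b) for _, b in cl.BIC_by_k]})")

pca = pca_ordination(occ)
print(f"PC1 {100 * pca.var_explained[0]:.1f}%  "
      f"PC2 {100 * pca.var_explained[1]:.1f}% of environmental variance")
X = occ.env().to_numpy()
X = (X - X.mean(0)) / X.std(0)
ratio, p = between_class_inertia(X, cl.assignments, n_rand=999,
                                 rng=np.random.default_rng(1))
print(f"between-class inertia = {ratio:.2f} (p = {p:.3f})")

lam, p_l, coef = dfa(occ, truth, pair=(0, 1))
print(f"DFA ecotype 0 vs 1: Wilks' lambda = {lam:.3f} (p = {p_l:.2e}); "
      f"top variable: {coef.abs().idxmax()}")

o1, o2 = occ.subset(truth == 0), occ.subset(truth == 1)
rng = np.random.default_rng(3)
m1, m2 = fit_sdm(o1, raster, rng=rng), fit_sdm(o2, raster, rng=rng)
train, test = evaluate_auc(m1, o1, raster, rng=rng)
print(f"SDM ecotype 0: training AUC {train:.3f}, test AUC {test:.3f}")

D, I = niche_overlap(m1.predict(raster), m2.predict(raster))
res = identity_test(o1, o2, raster, n_reps=20, rng=np.random.default_rng(4))
print(f"overlap: Schoener's D = {D:.3f}, Warren's I = {I:.3f}; "
      f"identity test p_D = {res.p_D:.3f}, p_I = {res.p_I:.3f}")

env = raster.env_matrix()
bg = np.random.default_rng(5).choice(len(env), size=(2, 500))
bt = background_test(o1, o2, env[bg[0]], env[bg[1]], n_resamples=500,
                     n_perm=2000, rng=np.random.default_rng(6))
print("background divergence test (per retained PCA axis):")
for ax in bt.per_axis:
    lo, hi = ax["d_b_CI"]
    print(f"  PC{ax['axis']}: d_n = {ax['d_n_mean']:.2f}  "
          f"d_b 95% CI = [{lo:.2f}, {hi:.2f}]  p = {ax['d_n_p']:.4f}  "
          f"-> {ax['verdict']}")
print()
print("Low overlap with an identity test rejecting equivalence, and d_n")
print("exceeding the background interval d_b, together indicate genuine")
print("niche divergence rather than mere habitat availability differences.")
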