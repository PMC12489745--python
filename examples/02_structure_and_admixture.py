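"""Population structure: PCA, cluster-number scan, DAPC, admixture.

Run:  python examples/02_structure_and_admixture.py
"""

import numpy as np

from popgea import (
    SimConfig,
    admixture_fit,
    align_Q,
    dapc_fit,
    kmeans_bic,
    pca_impute,
    simulate,
)

# five drifted populations, the survey-like shape
gm, _, truth = simulate(
    SimConfig(seed=3, n_pops=5, n_per_pop=40, n_loci=3000, fst_per_pop=0.15)
)

pca = pca_impute(gm, n_axes=20)
print("PCA: first two axes explain "
      f"{100 * pca.explained_frac[0]:.1f}% and {100 * pca.explained_frac[1]:.1f}% "
      "of the genotypic variance")

scan = kmeans_bic(pca.scores, k_max=20, n_starts=10, seed=0)
print(f"k-means/BIC scan over k = 1..20 chooses k = {scan.chosen_k} "
      "(the first BIC minimum before an increase)")

dapc = dapc_fit(pca.scores, gm.individuals["region"].to_numpy(), n_perm=30, seed=0)
print(f"DAPC keeps {dapc.best_n_pc} PCs (best a-score); "
      f"correct reassignment rate {dapc.reassignment_rate:.2f}; "
      f"LD1 explains {100 * dapc.explained_frac[0]:.1f}% of between-group variance")

# admixture proportions on a two-population subset, with CV over K
gm2, _, truth2 = simulate(
    SimConfig(seed=4, n_pops=2, n_per_pop=30, n_loci=600, fst_per_pop=0.3)
)
cv = {}
for K in (1, 2, 3):
    cv[K] = admixture_fit(gm2, K, seed=0, cv_folds=3, max_iter=300).cv_error
best = min(cv, key=cv.get)
print(f"\nadmixture cross-validation error by K: "
      + ", ".join(f"K={k}: {v:.3f}" for k, v in cv.items()))
fit = admixture_fit(gm2, best, seed=0, max_iter=500)
Qa = align_Q(fit.Q, truth2.Q.to_numpy())
mae = np.abs(Qa - truth2.Q.to_numpy()).mean()
print(f"best K = {best}; mean |Q - trueQ| = {mae:.3f} "
      "(ancestry fractions recovered from genotypes alone)")
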