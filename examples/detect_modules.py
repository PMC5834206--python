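"""Detect genetic modules among query strains from interaction-profile
correlations, including an anti-correlated (sign-flipped) module.

Two planted modules, the second carrying the exact negation of the first's
interaction profile — the situation where two physically coupled subunits
act in genetically opposite directions.  The pipeline correlates profiles,
votes on the cluster number k with three diagnostics (WSS elbow, average
silhouette, gap statistic), clusters, and projects onto two principal
components.
"""

import numpy as np

from emapnet import (
    SimulationConfig,
    adjusted_rand_index,
    correlate_profiles,
    pca_correlations,
    select_k,
    simulate_scores,
)

config = SimulationConfig(
    n_queries=20,
    n_tests=1536,
    conditions=("untreated",),
    n_modules=2,
    anti_module=("M2", "M1"),  # module 2 = negation of module 1
    interaction_sparsity=0.1,
    effect_sd=5.0,
    noise_sd=1.0,
    seed=3,
)
matrices, truth = simulate_scores(config)
corr = correlate_profiles(matrices["untreated"])

labels_true = np.array(truth.labels_for(corr.queries))
cross = corr.r[np.ix_(labels_true == "M1", labels_true == "M2")]
print(f"within-module correlation:  {corr.r[np.ix_(labels_true == 'M1', labels_true == 'M1')][np.triu_indices((labels_true == 'M1').sum(), 1)].mean():+.2f}")
print(f"between anti-modules:       {cross.mean():+.2f}  (sign-flipped profiles)")

assignment = select_k(corr, k_range=range(1, 8), seed=3)
print(f"\nk votes: {assignment.method['votes']} -> k = {assignment.k}")
ari = adjusted_rand_index(
    [assignment.labels[q] for q in corr.queries], labels_true
)
print(f"adjusted Rand index vs planted modules: {ari:.2f}")

pca = pca_correlations(corr)
print(f"\nPCA of the correlation matrix: PC1/PC2 explain "
      f"{pca.variance_explained[0]:.0%} / {pca.variance_explained[1]:.0%} of variance")
m1 = pca.coordinates[labels_true == "M1", 0].mean()
m2 = pca.coordinates[labels_true == "M2", 0].mean()
print(f"module means on PC1: M1 = {m1:+.2f}, M2 = {m2:+.2f}")
print("\nan ARI of 1.0 means the correlation/k-means pipeline recovered the")
print("planted subunit modules exactly; the opposite PC1 signs show the")
print("anti-correlated module separating along the first component.")
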