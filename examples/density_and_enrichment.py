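"""Ask whether a gene set is unusually connected to a query module, and
which gene sets the module's interaction partners are enriched for.

Network density between a query module and a gene set is the fraction of
measured query x test pairs carrying a significant interaction.  Its
significance comes from a Monte Carlo randomization test (random same-size
gene sets from the test library); enrichment of the module's significant
partners uses the upper-tail hypergeometric test with the test library as
background and Benjamini-Hochberg control.
"""

import numpy as np

from emapnet import (
    GeneSetCollection,
    SimulationConfig,
    call_significant,
    density_randomization_test,
    hypergeometric_enrichment,
    simulate_scores,
)

config = SimulationConfig(
    n_queries=20,
    n_tests=800,
    conditions=("untreated",),
    n_modules=4,
    interaction_sparsity=0.05,
    effect_sd=5.0,
    seed=11,
)
matrices, truth = simulate_scores(config)
calls = call_significant(matrices["untreated"], mode="static")

# the planted support of module M1 plays the role of a known pathway
tests = matrices["untreated"].tests
pathway = [tests[j] for j in truth.module_supports["M1"]]
module_queries = [q for q, m in truth.true_module.items() if m == "M1"]

result = density_randomization_test(
    calls, module_queries, pathway, n_permutations=100_000, seed=11
)
print(f"module M1 x pathway: density = {result.observed_density:.3f} "
      f"(null mean {result.null_mean:.3f} +- {result.null_sd:.3f})")
print(f"Monte Carlo p = {result.p_value:.2g} over {result.n_permutations} permutations")

# enrichment of M1's significant partners among three candidate sets
hits = [t for j, t in enumerate(tests)
        if (calls.calls[[calls.queries.index(q) for q in module_queries], j] != 0).any()]
rng = np.random.default_rng(0)
annotations = GeneSetCollection(sets={
    "planted_pathway": pathway,
    "random_set_a": list(rng.choice(tests, 40, replace=False)),
    "random_set_b": list(rng.choice(tests, 40, replace=False)),
})
for r in hypergeometric_enrichment(hits, annotations, background=tests):
    print(f"  {r.term}: overlap {r.overlap}/{r.term_size}, "
          f"p = {r.p_value:.2g}, BH-adjusted p = {r.adjusted_p:.2g}")
print("\nthe planted pathway shows density far above the permutation null and")
print("a tiny adjusted p, while random same-size sets sit at the null - the")
print("pattern used to tie a chromatin-remodeler module to a signaling pathway.")
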