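"""Build a differential genetic-interaction network between two conditions.

Simulates a screen in which half of the planted interactions are present
only under treatment, subtracts the untreated S-scores from the treated
ones (robustly standardized back to single-condition score units), applies
the differential cutoffs |D| >= 3, and reports how many of the planted
treated-only interactions the differential network recovers.
"""

import numpy as np

from emapnet import (
    SimulationConfig,
    call_significant,
    compute_differential,
    simulate_scores,
    tally_by_query,
)

config = SimulationConfig(
    n_queries=54,
    n_tests=1536,
    conditions=("untreated", "treated"),
    n_modules=4,
    interaction_sparsity=0.1,
    effect_mean=6.0,
    effect_sd=1.0,
    differential_fraction=0.5,  # half the planted pairs are treated-only
    seed=7,
)
matrices, truth = simulate_scores(config)
diff = compute_differential(matrices["treated"], matrices["untreated"])
calls = call_significant(diff, mode="differential")

qi = {q: i for i, q in enumerate(diff.queries)}
ti = {t: j for j, t in enumerate(diff.tests)}
planted = [(qi[q], ti[t]) for q, t in truth.differential_only if not diff.mask[qi[q], ti[t]]]
recovered = sum(abs(diff.scores[i, j]) >= 3.0 for i, j in planted)

print(f"raw-difference robust spread sigma_delta = {diff.sigma_delta:.3f} "
      f"(~sqrt(2) for two well-calibrated screens)")
print(f"differential network: {calls.n_significant()} significant pairs "
      f"({calls.n_positive()} positive, {calls.n_negative()} negative) at |D| >= 3")
print(f"planted treated-only interactions recovered: {recovered}/{len(planted)} "
      f"({recovered / len(planted):.1%})")

tally = tally_by_query(calls, normalize=True, condition="differential")
top = tally.table.nlargest(3, "n_total")
print("\nqueries with the most condition-specific interactions:")
for row in top.itertuples(index=False):
    print(f"  {row.query}: {row.n_total} calls (rankit {row.rankit:+.2f})")
print("\nthese hub queries are the strains whose genetic neighbourhood is")
print("most rewired by the treatment - the differential screen's headline result.")
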