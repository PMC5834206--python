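# emapnet

Differential epistatic-miniarray (EMAP) network analysis for yeast genetic
interaction screens: S-score computation from colony sizes, static and
differential interaction networks, genetic-module detection from
interaction-profile correlations, Monte Carlo network-density testing, and
background-corrected gene-set enrichment — plus a synthetic screen
generator with planted ground truth that makes the whole pipeline testable
end to end.

## Who this is for

EMAPs cross a panel of *query* mutants (e.g. chromatin-remodeling subunits
and metabolic signaling genes) against a large library of *test* mutants
and read out double-mutant fitness from pinned colony sizes, in one or
more growth conditions (untreated, rapamycin, ethanol, ...).  `emapnet` is
for analysts of such screens who need the quantitative layer between raw
colony sizes and biological claims: which pairs interact, which
interactions are condition-specific, which queries form functional modules,
and whether a module's connectivity to a pathway is more than chance.

## The statistics at the core

**S-score.** For each (query *q*, test *t*) pair with replicate colony
sizes, observed fitness is o_r = size_r / C0 (C0 = wild-type reference
size) and the neutral expectation is the multiplicative model e = f_q · f_t
from the parental single-mutant fitnesses.  Then

    S = (mean(o) − e) / sqrt((s² + s²_floor) / n)

with s² the replicate sample variance and s²_floor a self-calibrating
moderation term chosen so that null S-scores have unit variance (see
`docs/methods.md`).  Positive S = alleviating/epistatic, negative S =
aggravating/synthetic-sick.  Significance cutoffs: **S ≥ 2.0 or S ≤ −2.5**
(static conditions).

**Differential score.** Between a treated and an untreated screen,
Δ = S_treated − S_untreated is standardized robustly back to
single-condition score units, D = √2 · Δ / σ̂_Δ with σ̂_Δ = 1.4826 · MAD(Δ),
and called at **|D| ≥ 3.0** — the wider cutoff absorbs the √2 noise of a
difference of two screens.

**Modules.** Queries are correlated pairwise (Pearson, pairwise-complete)
across the test library; the rows of the query×query correlation matrix
are clustered hierarchically (average linkage on 1 − r) and by k-means,
with k chosen by majority vote of the within-SS elbow, average silhouette,
and gap statistic.  PCA of the correlation matrix provides the standard
two-component view.

**Network density.** density = significant pairs / measured pairs between a
query set and a test gene set; significance by Monte Carlo randomization
(random same-size gene sets from the test library, default 100,000
permutations, one-sided p with the +1 correction).

**Enrichment.** Upper-tail hypergeometric test of a hit list against
annotation terms with the EMAP test library as background, Benjamini–
Hochberg adjusted.

**Rankit normalization.** Per-query interaction tallies are made comparable
across conditions via Φ⁻¹((r − 0.5)/n) on the ranked counts.

## Worked example

`examples/differential_network.py` simulates a 54-query × 1536-test screen
in two conditions in which half of the planted interactions exist only
under treatment, then builds and thresholds the differential network:

```
raw-difference robust spread sigma_delta = 1.501 (~sqrt(2) for two well-calibrated screens)
differential network: 5675 significant pairs (2951 positive, 2724 negative) at |D| >= 3
planted treated-only interactions recovered: 3793/3998 (94.9%)

queries with the most condition-specific interactions:
  Q027: 118 calls (rankit +2.36)
  Q016: 116 calls (rankit +1.68)
  Q045: 116 calls (rankit +1.68)
```

σ̂_Δ ≈ √2 confirms both screens contribute ~unit null noise; ~95% of the
planted condition-specific interactions clear the |D| ≥ 3 cutoff; and the
rankit-normalized tally ranks the queries whose genetic neighbourhood the
treatment rewires most.  The other scripts in `examples/` cover scoring
and null calibration, module detection with an anti-correlated module,
density testing + enrichment, the one-config full pipeline
(`emapnet run --config run.yaml` does the same from the shell), and
re-analysis of a user-supplied deposited score table.

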