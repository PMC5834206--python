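# Methods

This note documents the models, estimators, numerical choices and known
limitations of `emapnet`.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Interaction scoring

### Model

A double mutant (query *q*, test *t*) is pinned as *n* replicate colonies
(default 4, the standard pinning density).  Observed fitness per replicate
is o_r = size_r / C0; the neutral expectation is the multiplicative model
e = f_q · f_t, the standard null for genetic-interaction screens (fitness
defects multiply when genes act independently).  The interaction statistic
is

    S = (mean(o) − e) / sqrt((s² + s²_floor) / n)

where s² is the replicate sample variance.  The published screens this
package re-implements used an unpublished MATLAB toolbox for this step;
`emapnet`'s scorer is therefore specified by its *calibration contract* —
null mean ≈ 0, null SD ≈ 1 — rather than numeric identity with that
toolbox.  Calibration is what makes the significance cutoffs portable.

### Reference colony size C0

C0 is the mean of size/(f_q·f_t) over all measured replicates.  The mean
(not the median) is used because under multiplicative unit-mean noise it is
exactly unbiased; the median of the right-skewed size distribution sits
~1% low, which would shift every null S-score by about +0.07.  Interacting
pairs perturb the estimate only at second order (they are sparse and their
effect signs approximately symmetric).  A known C0 can be supplied instead.

### Variance floor

A per-pair t-denominator with n = 4 has heavy tails (null SD ≈ √3), and
pairs with accidentally tiny s² explode.  The floor is an additive
moderation s²_floor = c · median(s² over pairs), with the weight c solved
at call time from

    E[ 1 / (X + c · median(X)) ] = 1,   X ~ χ²_{n−1} / (n−1),

the condition that null S have exactly unit variance under Gaussian
replicate noise (c ≈ 0.45 at n = 4; the expectation is evaluated on a
200,000-point quantile grid and solved by Brent's method).  Setting
`variance_floor=0.0` recovers the plain sqrt(s²/n) denominator for hand
calculations.

### Centering

S is finally centered on its library-wide median (robust to the sparse
interacting minority), mirroring the normalization step of standard EMAP
toolboxes.  The residual skew of the log-normal colony noise couples the
replicate mean and variance and would otherwise leave a systematic null
mean of about −0.06; after centering the measured null mean is −0.03 ±
0.01 with SD 1.01 ± 0.01 (20 seeds, 10⁴ pairs — recomputed by the test
suite at one seed).

### Degenerate inputs

Pairs with < 2 replicates are masked with a logged warning.  A pair whose
replicates all equal the expectation exactly is a perfect null (S = 0),
not 0/0.  A zero or negative C0 is an error.

## Significance calls

Static cutoffs are the asymmetric pair +2.0 / −2.5 (alleviating
interactions are noisier upward, so the aggravating cutoff is stricter);
differential cutoffs are ±3.0.  Calls are inclusive (score exactly at the
cutoff is called) and masked pairs are never called.  Both pairs are
configurable for sensitivity analyses.

## Differential networks

The differential score between a treated and an untreated screen is

    D = √2 · Δ / σ̂_Δ,   Δ = S_treated − S_untreated,
    σ̂_Δ = 1.4826 · MAD(Δ over unmasked pairs).

Rationale: two well-calibrated screens contribute unit null variance each,
so Δ has null SD √2; dividing by σ̂_Δ/√2 standardizes D back to
*single-condition* score units while staying robust to the heavy tails the
interacting pairs put on Δ.  On this scale a condition-specific
interaction of score magnitude m appears at D ≈ m, and the wider ±3.0
differential cutoff (vs +2.0/−2.5 static) is exactly the allowance for the
√2 null noise of a difference of screens.  (Normalizing D to unit null SD
instead would leave a magnitude-6 condition-specific effect at
D ≈ 6/√2 ≈ 4.24 and only Φ(4.24 − 3) ≈ 89% of such pairs called — and
would make the wider differential cutoffs inexplicable.)  σ̂_Δ is recorded
in the result; pairs masked in either parent stay masked; if MAD(Δ) = 0
the scale falls back to the SD, then to the raw difference, so that
D(X, X) ≡ 0 exactly.

## Rankit normalization

output_i = Φ⁻¹((r_i − 0.5)/n), ranks 1-based ascending, ties given the
mean of their ranks.  n = 1 maps to Φ⁻¹(0.5) = 0.  Used to put per-query
significant-interaction tallies from screens of different breadth on a
common normal scale.

## Module detection

*Features.*  Queries are correlated pairwise (Pearson) over
pairwise-complete unmasked tests; pairs sharing fewer than 30 tests are
masked with a warning.  Clustering and PCA operate on the **rows of the
query×query correlation matrix** — each query is represented by its
vector of relationships to every other query — which is the representation
the published module figures use.

*Hierarchical.*  Average linkage on d = 1 − r (the least
structure-imposing standard linkage; recorded in the method record).
`cut_largest_gap` cuts at the largest jump between successive merge
heights.

*k-means.*  Lloyd's algorithm, best of 50 random starts, tolerance 1e-8,
max 300 iterations, seeded (scikit-learn backend; empty clusters are
re-seeded by the backend).

*Choosing k.*  Three diagnostics over the scanned k range: the elbow
(argmax of the second difference of within-cluster SS), the average
silhouette (argmax, k ≥ 2), and the gap statistic — Tibshirani's
uniform-bounding-box reference, B = 50 references, log-WSS form, reference
k-means with 5 starts, SE inflated by sqrt(1 + 1/B), choosing the smallest
k with Gap(k) ≥ Gap(k+1) − SE(k+1).  The reported k is the majority vote,
ties resolved toward smaller k.  All three curves are stored in the
diagnostics table: the vote is a starting point, and published analyses
additionally weigh structural knowledge of the complexes — that judgment
is deliberately surfaced, not automated.  If the best silhouette over
k ≥ 2 is below 0.25 the assignment is flagged "no module support";
all-identical rows return k = 1 with a warning.

*PCA.*  Column-centered correlation rows projected on the top-2 right
singular vectors; variance-explained fractions reported; component signs
fixed by making the first query's loading non-negative so coordinates are
reproducible.

## Network density and its null

density = significant pairs / *measured* pairs in the query-set ×
test-set rectangle (masked pairs leave both numerator and denominator).  A
direction filter restricts the numerator to positive or negative calls;
the default counts both (the split is reported where a figure calls for
it).

The randomization test resamples the *test-gene set*: null draws are
uniform same-size subsets of the full test library, query set and call
mask fixed — answering "is this gene set's connectivity to these queries
higher than a random same-size gene set's?", the convention for
set-connectivity nulls.  Default 100,000 permutations; one-sided
upper-tail p = (1 + #{null ≥ observed}) / (1 + B), never zero.  An
alternative scheme that permutes call entries is available behind a flag
for sensitivity analysis.  For small libraries `exact_density_test`
enumerates all subsets and serves as the oracle.

The type-I calibration study (40 queries × 1000 tests, gene set of 150,
iid standard-normal scores, static cutoffs, 999 permutations per
repetition, 1000 repetitions) is sized so that the discreteness of the
count-valued density statistic — which makes the +1-corrected permutation
p conservative by up to one pmf step at the rejection boundary — costs
well under one percentage point of level: expected count ≈ 173 gives a
step ≈ 0.008 against the nominal 0.05.

## Enrichment

Upper-tail hypergeometric P(X ≥ overlap) with population = the EMAP test
library (the background a screen actually interrogated — using a
whole-genome background would inflate every enrichment), successes =
|term ∩ background|, draws = |hit list|.  A hit outside the background is
an error, not a silent drop.  Terms with overlap < 2 are reported but
flagged.  Benjamini–Hochberg adjustment across all tested terms
(statsmodels backend); note BH is *not* idempotent — reapplying it can
only inflate adjusted values — so adjusted p-values are reported once.

## Synthetic screens

The generator emulates the study geometry: 54 queries × 1536 tests, two
conditions, 4 replicates.  Queries split into modules; each module plants
interactions on a fraction π (default 0.1) of tests with signed magnitudes
|Normal(μ, τ)| shared by all module members, so within-module profiles
correlate by construction (expected r = π·E[ε²] / (π·E[ε²] + σ²) ≈ 0.71 at
τ/σ = 5, π = 0.1).  An *anti-module* carries the negation of another
module's profile, modelling physically coupled subunits with genetically
opposite signatures.  A fraction δ of each module's planted pairs (default
0.25) is *treated-only*: ε = 0 in the untreated baseline.  Two observation
layers:

* **score layer** — score = ε + Normal(0, σ): unit tests target
  downstream stages without scorer noise;
* **colony layer** — single-mutant fitnesses Normal(1, 0.1) truncated to
  (0, ∞) per strain (shared across conditions); expected double-mutant
  size C0 · f_q · f_t · g(ε) with g(ε) = 1 + κ·ε clipped below at 0.01;
  replicate sizes multiply by log-normal noise parameterized to **unit
  mean** and CV `colony_noise_cv` (default 0.15, a typical colony-pinning
  CV) — the unit-mean parameterization keeps the null exactly centered.
  κ is calibrated by a one-time cached internal simulation (analytic
  first-order guess, then one slope-correction pass) so the scorer
  recovers ε in expectation; the constant is stored in the ground truth.

2% of pairs are masked at random (failed pins).  All randomness flows
through `numpy.random.default_rng` (PCG64), one seed per dataset.

A fixed benchmark battery (`make_benchmark_suite`) pins the four study
conditions the tests assert on: (i) four modules at τ/σ = 5; (ii) two
modules, one the anti-module; (iii) a null screen (π = 0); (iv) a
differential screen with δ = 0.5 and effect magnitudes centred at 6σ.

**What the generator does not emulate:** plate-spatial artifacts (edge
effects, gradients), batch structure, linkage (same-chromosome) masking,
replicate outliers, and condition-dependent single-mutant fitness — all
handled upstream by the screening toolbox in real data.  Passing the
recovery suite therefore demonstrates the statistical machinery is correct
and calibrated under the stated noise model, not that raw plates from any
instrument can be fed in unnormalized.

## Pipeline

One YAML config drives simulate/score → differential → tallies → modules
→ density test → enrichment.  Every random stage takes an explicit seed
(no global RNG); outputs are TSV ("NA" missing token, identifiers
case-sensitive, matrices self-describing via `#` header comments carrying
condition and thresholds, ≥17 significant digits so round trips are
bit-exact); the manifest records a config snapshot, package version, seeds
and per-file sha256 checksums, and a stage whose outputs already match
their recorded checksums is skipped on rerun.  Config validation collects
*all* errors before any stage runs.

## Problem sizes used by the validation suite

Chosen to make each property measurable with comfortable margins: null
calibration at 10⁴ pairs; differential recovery and module recovery over
100 seeded 54×1536 screens; the density oracle on a 5×8 library (all 56
subsets enumerable) with 100,000 Monte Carlo permutations; type-I error
over 1000 null screens at 999 permutations each; enrichment against exact
integer combinatorics on libraries ≤ 20.

## Known limitations

* The scorer is calibrated, not toolbox-identical: absolute S values from
  other pipelines may differ by a monotone rescaling.
* Pairwise-complete correlations are not positive-semidefinite in
  pathological missingness patterns; the module stages require the
  correlation submatrix to be fully observed and say so.
* The gap statistic uses the uniform bounding-box reference; rotated
  (PCA-aligned) references can differ for strongly elongated clusters.
* Density resampling treats test genes as exchangeable; if a gene set is
  concentrated in a systematically better-measured part of the library,
  the null is optimistic.  The `permute_calls` scheme is the cross-check.
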