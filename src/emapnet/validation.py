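"""Self-validation studies: calibration and planted-structure recovery.

Each function runs one study end to end through the public API — generating
its own synthetic inputs, executing the method, and measuring the result —
and returns plain numbers.  The studies double as the package's acceptance
surface: the test suite asserts on them and ``scripts/acceptance.py``
reports them.

All studies are seeded; the same seed reproduces the same numbers exactly.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import stats

from .io_formats import InteractionMatrix
from .modules import adjusted_rand_index, correlate_profiles, select_k
from .netstats import density_randomization_test, exact_density_test
from .scoring import (
    call_significant,
    compute_differential,
    compute_sscores,
    rankit_normalize,
)
from .synthetic import SimulationConfig, make_benchmark_suite, simulate_colonies, simulate_scores


def rankit_exactness(n: int = 10_000, seed: int = 0) -> float:
    """Max |rankit(x) - Phi^-1((r - 0.5)/n)| over a random distinct vector.

    The expected values are recomputed here from the defining formula via an
    argsort-based ranking, independent of the implementation's ranking path.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    out = rankit_normalize(x)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    expected = stats.norm.ppf((ranks - 0.5) / n)
    dev = float(np.max(np.abs(out - expected)))
    return max(dev, float(abs(rankit_normalize([42.0])[0])))  # n=1 -> 0 case


def sscore_null_calibration(
    seed: int = 0, n_pairs: int = 10_000, n_replicates: int = 4
) -> tuple[float, float, int]:
    """(mean, SD, n) of S on a null colony screen (no planted interactions)."""
    n_tests = n_pairs // 10
    config = SimulationConfig(
        n_queries=10,
        n_tests=n_tests,
        conditions=("untreated",),
        n_replicates=n_replicates,
        n_modules=1,
        interaction_sparsity=0.0,
        missing_fraction=0.0,
        seed=seed,
    )
    plates, _ = simulate_colonies(config)
    matrix = compute_sscores(plates, "untreated")
    s = matrix.scores[~matrix.mask]
    return float(s.mean()), float(s.std(ddof=0)), int(s.size)


def differential_identity(seed: int = 0) -> float:
    """Max |D| of the self-differential D(X, X): must be identically zero."""
    matrices, _ = simulate_scores(
        SimulationConfig(n_queries=10, n_tests=200, seed=seed)
    )
    x = matrices["untreated"]
    diff = compute_differential(x, x)
    return float(np.abs(diff.scores).max())


def differential_recovery(
    seed: int = 0, n_seeds: int = 100, cutoff: float = 3.0
) -> dict:
    """Recovery of planted treated-only interactions at |D| >= cutoff.

    Uses the benchmark differential case (effect magnitudes centred at 6 on
    the score scale, unit score noise, half of planted pairs treated-only);
    one fresh screen per seed.  Returns the aggregate call rate over all
    planted treated-only pairs, the per-seed minimum, and the number of
    seeds whose own rate reaches 0.9.
    """
    base = make_benchmark_suite(seed)[3].config
    rates = []
    for i in range(n_seeds):
        config = replace(base, seed=seed + i)
        matrices, truth = simulate_scores(config)
        diff = compute_differential(matrices["treated"], matrices["untreated"])
        qi = {q: k for k, q in enumerate(diff.queries)}
        ti = {t: k for k, t in enumerate(diff.tests)}
        called = total = 0
        for q, t in truth.differential_only:
            i_, j_ = qi[q], ti[t]
            if diff.mask[i_, j_]:
                continue
            total += 1
            called += abs(diff.scores[i_, j_]) >= cutoff
        rates.append(called / total)
    rates = np.asarray(rates)
    return {
        "mean_rate": float(rates.mean()),
        "min_rate": float(rates.min()),
        "n_seeds_ge_90pct": int((rates >= 0.9).sum()),
        "n_seeds": n_seeds,
    }


def module_recovery(seed: int = 0, n_seeds: int = 100) -> dict:
    """Planted four-module recovery: select_k vote and k-means ARI per seed."""
    base = make_benchmark_suite(seed)[0].config
    k_true = base.n_modules
    n_k_correct = n_ari_ok = 0
    aris = []
    for i in range(n_seeds):
        config = replace(base, seed=seed + i)
        matrices, truth = simulate_scores(config)
        corr = correlate_profiles(matrices[config.conditions[0]])
        assignment = select_k(corr, k_range=range(1, 9), seed=seed + i)
        labels_true = truth.labels_for(corr.queries)
        labels_found = [assignment.labels[q] for q in corr.queries]
        ari = adjusted_rand_index(labels_found, labels_true)
        aris.append(ari)
        n_k_correct += assignment.k == k_true
        n_ari_ok += ari >= 0.9
    return {
        "k_true": k_true,
        "n_k_correct": n_k_correct,
        "n_ari_ge_0.9": n_ari_ok,
        "mean_ari": float(np.mean(aris)),
        "n_seeds": n_seeds,
    }


def anti_module_recovery(seed: int = 0, n_seeds: int = 10) -> dict:
    """Two-module case with one anti-module: select_k = 2 and strong
    anti-correlation between the module and its negated partner."""
    base = make_benchmark_suite(seed)[1].config
    n_k_correct = 0
    max_cross = []
    for i in range(n_seeds):
        config = replace(base, seed=seed + i)
        matrices, truth = simulate_scores(config)
        corr = correlate_profiles(matrices[config.conditions[0]])
        assignment = select_k(corr, k_range=range(1, 9), seed=seed + i)
        n_k_correct += assignment.k == 2
        labels = np.array(truth.labels_for(corr.queries))
        cross = corr.r[np.ix_(labels == "M1", labels == "M2")]
        max_cross.append(float(cross.max()))
    return {
        "n_k_correct": n_k_correct,
        "n_seeds": n_seeds,
        "max_cross_correlation": float(max(max_cross)),
    }


def _toy_calls(seed: int = 3):
    """Fixed 5x8 toy screen with a handful of significant interactions."""
    rng = np.random.default_rng(seed)
    scores = rng.normal(0, 1, (5, 8))
    scores[0, 0] = 4.0
    scores[1, 1] = -3.0
    scores[2, 0] = 2.5
    matrix = InteractionMatrix(
        queries=[f"q{i}" for i in range(5)],
        tests=[f"t{j}" for j in range(8)],
        condition="toy",
        scores=scores,
        mask=np.zeros((5, 8), dtype=bool),
    )
    return call_significant(matrix, mode="static")


def density_oracle_agreement(seed: int = 0, n_permutations: int = 100_000) -> dict:
    """Monte Carlo density p versus exhaustive enumeration on the 5x8 toy."""
    calls = _toy_calls()
    query_set = calls.queries
    test_set = ["t0", "t1", "t2"]
    mc = density_randomization_test(
        calls, query_set, test_set, n_permutations=n_permutations, seed=seed
    )
    exact = exact_density_test(calls, query_set, test_set)
    return {
        "mc_p": mc.p_value,
        "exact_p": exact,
        "abs_diff": abs(mc.p_value - exact),
        "n_permutations": n_permutations,
    }


def density_type1_error(
    seed: int = 0,
    n_reps: int = 1000,
    n_permutations: int = 999,
    alpha: float = 0.05,
    n_queries: int = 40,
    n_tests: int = 1000,
    set_size: int = 150,
) -> dict:
    """Empirical type-I error of the density randomization test.

    Each repetition draws an iid standard-normal score matrix (the null:
    the test-gene set is unrelated to the calls), applies static thresholds,
    and tests a fixed arbitrary gene set of ``set_size`` tests.
    """
    rng = np.random.default_rng(seed)
    queries = [f"q{i}" for i in range(n_queries)]
    tests = [f"t{j}" for j in range(n_tests)]
    test_set = tests[:set_size]
    rejections = 0
    for rep in range(n_reps):
        matrix = InteractionMatrix(
            queries=queries,
            tests=tests,
            condition="null",
            scores=rng.standard_normal((n_queries, n_tests)),
            mask=np.zeros((n_queries, n_tests), dtype=bool),
        )
        calls = call_significant(matrix, mode="static")
        result = density_randomization_test(
            calls,
            queries,
            test_set,
            n_permutations=n_permutations,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rejections += result.p_value <= alpha
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps, "alpha": alpha}


def demo_screen_significant_counts(seed: int = 0) -> dict:
    """Significant-interaction tallies on a default-geometry synthetic screen.

    Static calls in the untreated condition and differential calls between
    the treated and untreated screens, at the standard cutoffs.
    """
    config = SimulationConfig(seed=seed)
    matrices, _ = simulate_scores(config)
    static_calls = call_significant(matrices["untreated"], mode="static")
    diff = compute_differential(matrices["treated"], matrices["untreated"])
    diff_calls = call_significant(diff, mode="differential")
    return {
        "untreated_significant": static_calls.n_significant(),
        "differential_significant": diff_calls.n_significant(),
        "n_pairs": int((~static_calls.mask).sum()),
    }
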