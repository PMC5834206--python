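"""Network-connectivity statistics between query and test gene sets.

*Network density* between a query set and a test gene set is the number of
significant interactions divided by the total number of measured query-test
pairs.  Its significance is assessed by a Monte Carlo randomization test:
the test-gene set is resampled uniformly (same size, without replacement)
from the full test library with the query set and call mask held fixed,
which asks exactly "is this gene set's connectivity to these queries higher
than a random same-size gene set's?".  The default is 100,000 permutations
with a one-sided upper-tail p and the +1 correction, so p is never zero.

Gene-set enrichment of interaction partners uses the upper-tail
hypergeometric test with the EMAP test library as the background population
and Benjamini-Hochberg control across terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import EmapValidationError, GeneSetCollection
from .scoring import SignificanceCalls

logger = logging.getLogger(__name__)


def _rectangle(calls: SignificanceCalls, query_set, test_set):
    qs, ts = list(query_set), list(test_set)
    if not qs or not ts:
        raise EmapValidationError("query_set and test_set must be non-empty")
    q_lookup = {q: i for i, q in enumerate(calls.queries)}
    t_lookup = {t: j for j, t in enumerate(calls.tests)}
    bad_q = [q for q in qs if q not in q_lookup]
    bad_t = [t for t in ts if t not in t_lookup]
    if bad_q or bad_t:
        raise EmapValidationError(
            f"identifiers not on matrix axes: queries {bad_q}, tests {bad_t}"
        )
    qi = np.array([q_lookup[q] for q in qs])
    ti = np.array([t_lookup[t] for t in ts])
    return qi, ti


def _directional(calls_block: np.ndarray, direction: str) -> np.ndarray:
    if direction == "all":
        return calls_block != 0
    if direction == "positive":
        return calls_block == 1
    if direction == "negative":
        return calls_block == -1
    raise ValueError(f"direction must be all|positive|negative, got {direction!r}")


def network_density(
    calls: SignificanceCalls, query_set, test_set, direction: str = "all"
) -> float:
    """Significant pairs / measured pairs within the query_set x test_set rectangle."""
    qi, ti = _rectangle(calls, query_set, test_set)
    block = calls.calls[np.ix_(qi, ti)]
    measured = ~calls.mask[np.ix_(qi, ti)]
    denom = int(measured.sum())
    if denom == 0:
        raise EmapValidationError("no measured pairs in the rectangle")
    hits = _directional(block, direction) & measured
    return float(hits.sum() / denom)


@dataclass
class DensityTestResult:
    """Observed density, permutation-null summary and empirical p-value."""

    query_set: list[str]
    test_set: list[str]
    direction: str
    observed_density: float
    n_permutations: int
    null_mean: float
    null_sd: float
    null_quantiles: dict[str, float]
    p_value: float
    seed: int
    scheme: str = "resample_tests"


def density_randomization_test(
    calls: SignificanceCalls,
    query_set,
    test_set,
    n_permutations: int = 100_000,
    seed: int = 0,
    direction: str = "all",
    scheme: str = "resample_tests",
) -> DensityTestResult:
    """Monte Carlo randomization test for network density.

    ``scheme="resample_tests"`` (default) draws random test-gene sets of
    size |test_set| uniformly without replacement from the full test
    library, keeping the query set and call mask fixed.
    ``scheme="permute_calls"`` instead shuffles the call entries within the
    query rows (sensitivity analysis).  One-sided upper-tail
    p = (1 + #{null >= observed}) / (1 + n_permutations).
    """
    if n_permutations < 1:
        raise EmapValidationError("n_permutations must be >= 1")
    qi, ti = _rectangle(calls, query_set, test_set)
    n_library = len(calls.tests)
    size = len(ti)
    if size >= n_library:
        raise EmapValidationError("test_set must be smaller than the test library")
    observed = network_density(calls, query_set, test_set, direction)

    rng = np.random.default_rng(seed)
    hits_rows = _directional(calls.calls[qi], direction) & ~calls.mask[qi]
    measured_rows = ~calls.mask[qi]
    # Per-test-column contributions over the fixed query rows.
    hit_counts = hits_rows.sum(axis=0).astype(np.int64)
    measured_counts = measured_rows.sum(axis=0).astype(np.int64)

    null = np.empty(n_permutations)
    chunk = max(1, min(n_permutations, 20_000))
    if scheme == "resample_tests":
        done = 0
        while done < n_permutations:
            m = min(chunk, n_permutations - done)
            u = rng.random((m, n_library))
            subset = np.argpartition(u, size - 1, axis=1)[:, :size]
            num = hit_counts[subset].sum(axis=1)
            den = measured_counts[subset].sum(axis=1)
            null[done : done + m] = np.where(den > 0, num / np.maximum(den, 1), 0.0)
            done += m
    elif scheme == "permute_calls":
        flat_hits = hits_rows[measured_rows]  # measured cells only
        n_cells = flat_hits.size
        block_measured = measured_rows[:, np.isin(np.arange(n_library), ti)]
        n_block = int(block_measured.sum())
        for b in range(n_permutations):
            perm = rng.permutation(n_cells)
            null[b] = flat_hits[perm[:n_block]].sum() / n_block
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    n_ge = int(np.sum(null >= observed - 1e-12))
    p = (1 + n_ge) / (1 + n_permutations)
    qs = np.quantile(null, [0.5, 0.95, 0.99])
    return DensityTestResult(
        query_set=list(query_set),
        test_set=list(test_set),
        direction=direction,
        observed_density=observed,
        n_permutations=n_permutations,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=0)),
        null_quantiles={"q50": float(qs[0]), "q95": float(qs[1]), "q99": float(qs[2])},
        p_value=float(p),
        seed=seed,
        scheme=scheme,
    )


def exact_density_test(
    calls: SignificanceCalls, query_set, test_set, direction: str = "all"
) -> float:
    """Exact randomization p by full enumeration of all same-size test sets.

    Only feasible for small libraries; used as the oracle for the Monte
    Carlo test.  p = #{subsets with null density >= observed} / #subsets.
    """
    from itertools import combinations

    qi, ti = _rectangle(calls, query_set, test_set)
    observed = network_density(calls, query_set, test_set, direction)
    hits_rows = _directional(calls.calls[qi], direction) & ~calls.mask[qi]
    measured_rows = ~calls.mask[qi]
    hit_counts = hits_rows.sum(axis=0)
    measured_counts = measured_rows.sum(axis=0)
    n_ge = total = 0
    for subset in combinations(range(len(calls.tests)), len(ti)):
        idx = list(subset)
        den = measured_counts[idx].sum()
        dens = hit_counts[idx].sum() / den if den > 0 else 0.0
        n_ge += dens >= observed - 1e-12
        total += 1
    return n_ge / total


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """One term's hypergeometric enrichment among the hit genes."""

    term: str
    term_size: int  # |term ∩ background|
    overlap: int
    gene_hits: list[str]
    p_value: float
    adjusted_p: float
    flagged_small_overlap: bool = False


def hypergeometric_p(overlap: int, background: int, term_size: int, draws: int) -> float:
    """Upper-tail hypergeometric P(X >= overlap)."""
    return float(stats.hypergeom.sf(overlap - 1, background, term_size, draws))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1, monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_enrichment(
    gene_hits,
    annotations: GeneSetCollection,
    background,
    flag_overlap_below: int = 2,
) -> list[EnrichmentResult]:
    """Background-corrected gene-set enrichment of the hit genes.

    ``background`` is the gene universe (the EMAP test library); every
    annotation term is intersected with it before testing, and a hit outside
    the background is an error (silent background inflation would bias every
    p-value).  Terms with overlap below ``flag_overlap_below`` are reported
    but flagged.  Results are sorted by p-value, BH-adjusted across all
    tested terms.
    """
    hits = list(dict.fromkeys(gene_hits))
    bg = set(background)
    outside = [g for g in hits if g not in bg]
    if outside:
        raise EmapValidationError(f"hit genes not in background: {outside}")
    hit_set = set(hits)

    rows = []
    for term, members in annotations.items():
        in_bg = [m for m in members if m in bg]
        if not in_bg:
            logger.warning("term %r has no members in background; skipped", term)
            continue
        overlap_genes = [m for m in in_bg if m in hit_set]
        p = hypergeometric_p(len(overlap_genes), len(bg), len(in_bg), len(hits))
        rows.append((term, len(in_bg), overlap_genes, p))
    if not rows:
        return []
    adjusted = benjamini_hochberg([r[3] for r in rows])
    results = [
        EnrichmentResult(
            term=term,
            term_size=term_size,
            overlap=len(overlap_genes),
            gene_hits=overlap_genes,
            p_value=p,
            adjusted_p=float(adj),
            flagged_small_overlap=len(overlap_genes) < flag_overlap_below,
        )
        for (term, term_size, overlap_genes, p), adj in zip(rows, adjusted)
    ]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": [r.term for r in results],
            "term_size": [r.term_size for r in results],
            "overlap": [r.overlap for r in results],
            "p_value": [r.p_value for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
            "flagged_small_overlap": [r.flagged_small_overlap for r in results],
            "genes": ["|".join(r.gene_hits) for r in results],
        }
    )


def extract_subnetwork(calls: SignificanceCalls, query_set, test_set) -> pd.DataFrame:
    """Edge list (query, test, score, sign) of significant pairs in the rectangle.

    The row count equals the numerator of :func:`network_density` on the
    same inputs; suitable for TSV serialization and network plotting tools.
    """
    qi, ti = _rectangle(calls, query_set, test_set)
    rows = []
    for i in qi:
        for j in ti:
            if calls.mask[i, j] or calls.calls[i, j] == 0:
                continue
            rows.append(
                (
                    calls.queries[i],
                    calls.tests[j],
                    float(calls.scores[i, j]),
                    int(calls.calls[i, j]),
                )
            )
    return pd.DataFrame(rows, columns=["query", "test", "score", "sign"])
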