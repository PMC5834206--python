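"""Genetic-module inference from interaction-profile correlations.

Queries whose interaction profiles across the test library correlate
strongly are interpreted as acting in a shared function (a genetic module).
This module computes pairwise-complete Pearson correlations between query
profiles, clusters the *rows of the correlation matrix* (hierarchically and
by k-means), selects the cluster number k by majority vote of three
diagnostics — the within-cluster-sum-of-squares elbow, the average
silhouette, and the gap statistic — and projects the correlation rows onto
their first two principal components.

Using correlation-matrix rows (rather than raw 1500-dimensional profiles)
as feature vectors makes each query a vector of its relationships to every
other query, which is the representation the silhouette/gap/PCA diagnostics
are run on throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .io_formats import EmapValidationError, InteractionMatrix

logger = logging.getLogger(__name__)

#: Minimum shared unmasked tests for a correlation to be reported.
MIN_SHARED_TESTS = 30


@dataclass
class CorrelationProfile:
    """Pairwise Pearson correlations between query interaction profiles.

    ``r`` is symmetric with unit diagonal; ``n_shared[i, j]`` counts the
    tests unmasked in both profiles; ``masked`` flags pairs with too few
    shared tests to correlate reliably.
    """

    queries: list[str]
    r: np.ndarray
    n_shared: np.ndarray
    masked: np.ndarray

    @property
    def n_queries(self) -> int:
        return len(self.queries)

    def pair(self, a: str, b: str) -> float:
        i, j = self.queries.index(a), self.queries.index(b)
        return float(self.r[i, j])


def correlate_profiles(
    matrix: InteractionMatrix,
    query_subset: list[str] | None = None,
    min_shared: int = MIN_SHARED_TESTS,
) -> CorrelationProfile:
    """Pearson correlations between query profiles over pairwise-complete tests."""
    subset = query_subset if query_subset is not None else list(matrix.queries)
    if len(subset) < 2:
        raise EmapValidationError("need at least 2 queries to correlate")
    idx = matrix.query_index(subset)
    scores = matrix.scores[idx]
    present = ~matrix.mask[idx]
    n = len(subset)
    r = np.eye(n)
    n_shared = np.zeros((n, n), dtype=int)
    np.fill_diagonal(n_shared, present.sum(axis=1))
    masked = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            shared = present[i] & present[j]
            m = int(shared.sum())
            n_shared[i, j] = n_shared[j, i] = m
            if m < min_shared:
                masked[i, j] = masked[j, i] = True
                logger.warning(
                    "correlation (%s, %s) masked: only %d shared tests (< %d)",
                    subset[i], subset[j], m, min_shared,
                )
                continue
            x, y = scores[i, shared], scores[j, shared]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                rij = 0.0
            else:
                rij = float(np.corrcoef(x, y)[0, 1])
            r[i, j] = r[j, i] = rij
    return CorrelationProfile(queries=list(subset), r=r, n_shared=n_shared, masked=masked)


@dataclass
class ModuleAssignment:
    """Query -> module labels plus the diagnostics behind the choice of k."""

    labels: dict[str, str]
    k: int
    method: dict = field(default_factory=dict)
    diagnostics: pd.DataFrame | None = None  # k, wss, silhouette, gap, gap_se
    notes: list[str] = field(default_factory=list)

    def label_vector(self, queries: list[str]) -> np.ndarray:
        return np.array([self.labels[q] for q in queries])


def _check_unmasked(corr: CorrelationProfile, op: str) -> None:
    if corr.masked.any():
        pairs = np.argwhere(np.triu(corr.masked, 1))
        names = [(corr.queries[i], corr.queries[j]) for i, j in pairs[:5]]
        raise EmapValidationError(
            f"{op} requires a fully observed correlation matrix; masked pairs "
            f"(impute or drop queries): {names}"
        )


def cluster_hierarchical(corr: CorrelationProfile):
    """Average-linkage agglomerative clustering on distance d = 1 - r.

    Returns a scipy linkage matrix (merge tree with heights).  The merge
    order is deterministic for a given input order; ties in merge height are
    broken toward the lowest-index pair by scipy's nearest-neighbor chain.
    """
    _check_unmasked(corr, "hierarchical clustering")
    d = 1.0 - corr.r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return hierarchy.linkage(squareform(d, checks=False), method="average")


def cut_largest_gap(linkage_matrix: np.ndarray) -> np.ndarray:
    """Cut the dendrogram at the largest gap between successive merge heights."""
    heights = linkage_matrix[:, 2]
    if len(heights) == 1:
        return np.zeros(2, dtype=int)
    gaps = np.diff(heights)
    cut = (heights[np.argmax(gaps)] + heights[np.argmax(gaps) + 1]) / 2.0
    return hierarchy.fcluster(linkage_matrix, t=cut, criterion="distance")


def _features(corr: CorrelationProfile) -> np.ndarray:
    return corr.r.copy()


def kmeans_modules(
    corr: CorrelationProfile, k: int, n_starts: int = 50, seed: int = 0
) -> ModuleAssignment:
    """k-means (Lloyd) on correlation-matrix rows, best of ``n_starts`` starts."""
    _check_unmasked(corr, "k-means")
    n = corr.n_queries
    if not 1 <= k <= n:
        raise EmapValidationError(f"k must be in [1, {n}], got {k}")
    X = _features(corr)
    km = KMeans(
        n_clusters=k, n_init=n_starts, algorithm="lloyd", tol=1e-8,
        max_iter=300, random_state=seed,
    ).fit(X)
    labels = {q: f"C{lab + 1}" for q, lab in zip(corr.queries, km.labels_)}
    return ModuleAssignment(
        labels=labels,
        k=k,
        method={
            "algorithm": "kmeans-lloyd", "n_starts": n_starts, "seed": seed,
            "wss": float(km.inertia_), "features": "correlation-matrix rows",
        },
    )


def _wss_for_k(X: np.ndarray, k: int, n_starts: int, seed: int) -> float:
    if k == 1:
        return float(((X - X.mean(axis=0)) ** 2).sum())
    km = KMeans(
        n_clusters=k, n_init=n_starts, algorithm="lloyd", tol=1e-8,
        max_iter=300, random_state=seed,
    ).fit(X)
    return float(km.inertia_)


def gap_statistic(
    X: np.ndarray, k_range, seed: int, n_refs: int = 50, n_starts: int = 5,
    wss_obs=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gap statistic with uniform-bounding-box references, log-WSS form.

    Gap(k) = mean_b log W*_kb - log W_k over ``n_refs`` reference datasets
    drawn uniformly over the per-feature bounding box of X; the reported SE
    includes the sqrt(1 + 1/B) simulation-error inflation.  ``wss_obs``
    optionally supplies precomputed observed within-cluster SS per k.
    """
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    if wss_obs is None:
        wss_obs = [_wss_for_k(X, k, 50, seed) for k in k_range]
    log_w_obs = np.log(np.asarray(wss_obs, dtype=float))
    log_w_ref = np.empty((n_refs, len(list(k_range))))
    for b in range(n_refs):
        ref = rng.uniform(lo, hi, size=X.shape)
        ref_seed = int(rng.integers(0, 2**31 - 1))
        for ki, k in enumerate(k_range):
            log_w_ref[b, ki] = np.log(_wss_for_k(ref, k, n_starts, ref_seed))
    gap = log_w_ref.mean(axis=0) - log_w_obs
    se = log_w_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / n_refs)
    return gap, se


def select_k(
    corr: CorrelationProfile,
    k_range=range(1, 9),
    seed: int = 0,
    n_starts: int = 50,
    n_refs: int = 50,
) -> ModuleAssignment:
    """Choose the cluster number by majority vote of three diagnostics.

    * elbow: argmax of the second difference of the WSS curve;
    * silhouette: argmax of the average silhouette (k >= 2);
    * gap: smallest k with Gap(k) >= Gap(k+1) - SE(k+1).

    Ties (no majority) resolve toward the smallest voted k.  If the best
    silhouette over k >= 2 is below 0.25 the assignment is flagged
    ``no module support`` — the vote is still reported, but the data show
    no convincing cluster structure.  Degenerate input (all rows identical)
    returns k = 1 with a warning.
    """
    _check_unmasked(corr, "select_k")
    X = _features(corr)
    n = corr.n_queries
    ks = [k for k in k_range if 1 <= k <= n - 1]
    if not ks:
        raise EmapValidationError(f"k_range {list(k_range)} outside [1, {n - 1}]")

    if np.allclose(X, X[0], atol=1e-12):
        logger.warning("all correlation rows identical; returning k = 1")
        return ModuleAssignment(
            labels={q: "C1" for q in corr.queries}, k=1,
            method={"algorithm": "degenerate"}, notes=["degenerate: identical rows"],
        )

    wss = np.empty(len(ks))
    sil = np.full(len(ks), np.nan)
    for ki, k in enumerate(ks):
        if k == 1:
            wss[ki] = float(((X - X.mean(axis=0)) ** 2).sum())
            continue
        km = KMeans(
            n_clusters=k, n_init=n_starts, algorithm="lloyd", tol=1e-8,
            max_iter=300, random_state=seed,
        ).fit(X)
        wss[ki] = float(km.inertia_)
        if len(np.unique(km.labels_)) > 1:
            sil[ki] = silhouette_score(X, km.labels_)
    gap, gap_se = gap_statistic(X, ks, seed=seed, n_refs=n_refs, wss_obs=wss)

    votes: dict[str, int] = {}
    if len(ks) >= 3:
        second_diff = wss[:-2] - 2 * wss[1:-1] + wss[2:]
        votes["elbow"] = ks[1 + int(np.argmax(second_diff))]
    if np.any(np.isfinite(sil)):
        votes["silhouette"] = ks[int(np.nanargmax(sil))]
    gap_k = ks[-1]
    for ki in range(len(ks) - 1):
        if gap[ki] >= gap[ki + 1] - gap_se[ki + 1]:
            gap_k = ks[ki]
            break
    votes["gap"] = gap_k

    counts: dict[int, int] = {}
    for k in votes.values():
        counts[k] = counts.get(k, 0) + 1
    best = max(counts.values())
    chosen = min(k for k, c in counts.items() if c == best)

    notes = []
    finite_sil = sil[np.isfinite(sil)]
    if finite_sil.size and finite_sil.max() < 0.25:
        notes.append("no module support")
        logger.warning("max silhouette %.3f < 0.25: no module support", finite_sil.max())

    assignment = kmeans_modules(corr, chosen, n_starts=n_starts, seed=seed)
    assignment.method.update({"votes": votes, "k_range": list(ks)})
    assignment.diagnostics = pd.DataFrame(
        {"k": ks, "wss": wss, "silhouette": sil, "gap": gap, "gap_se": gap_se}
    )
    assignment.notes = notes
    return assignment


@dataclass
class PCAResult:
    """Top-2 principal-component projection of the correlation rows."""

    queries: list[str]
    coordinates: np.ndarray  # (n, 2)
    components: np.ndarray  # (2, n_features), orthonormal
    variance_explained: np.ndarray  # fractions, non-increasing


def pca_correlations(corr: CorrelationProfile) -> PCAResult:
    """Center the correlation-matrix columns and project onto the top-2 PCs.

    Component signs are fixed by making each component's loading on the
    first query non-negative, so coordinates are reproducible across runs.
    """
    _check_unmasked(corr, "PCA")
    if corr.n_queries < 3:
        raise EmapValidationError("PCA requires at least 3 queries")
    X = _features(corr)
    Xc = X - X.mean(axis=0)
    # SVD of the centered matrix == eigendecomposition of the covariance
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / max(corr.n_queries - 1, 1)
    total = var.sum()
    frac = var / total if total > 0 else var
    comps = Vt[:2].copy()
    coords = Xc @ comps.T
    for c in range(2):
        if comps[c, 0] < 0:
            comps[c] *= -1.0
            coords[:, c] *= -1.0
    return PCAResult(
        queries=list(corr.queries),
        coordinates=coords,
        components=comps,
        variance_explained=frac[:2],
    )


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings (order-independent)."""
    from sklearn.metrics import adjusted_rand_score

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(adjusted_rand_score(list(labels_a), list(labels_b)))
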