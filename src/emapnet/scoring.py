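"""Genetic-interaction scoring: S-scores, significance calls, differential
networks, rankit normalization, and per-query interaction tallies.

The S-score compares the observed double-mutant fitness, inferred from
replicate colony sizes, with the multiplicative expectation from the two
parental single-mutant fitnesses:

    S = (mean(o) - f_q * f_t) / sqrt((s^2 + floor) / n)

where o_r = size_r / C0 is the colony size normalized to the wild-type
reference C0, s^2 is the replicate sample variance, and ``floor`` is a
moderation term that stops pairs with accidentally tiny replicate variance
from producing huge scores.  The floor is self-calibrating: it is chosen so
that, under Gaussian replicate noise, null S-scores have unit variance (see
:func:`variance_floor_weight`).  The calibration — null mean ~ 0, null
SD ~ 1 — is the contract of this scorer, so the static significance cutoffs
(S >= 2.0 alleviating, S <= -2.5 aggravating) and differential cutoffs
(|D| >= 3.0) are interpretable on a common scale.

A differential score between a treated and an untreated screen is the
per-pair difference of S-scores, robustly standardized back to
single-condition score units:

    D = sqrt(2) * (S_treated - S_untreated) / sigma_delta,
    sigma_delta = 1.4826 * MAD(S_treated - S_untreated)

Since two independent screens each contribute unit null variance to the
difference, sigma_delta ~ sqrt(2) for a well-calibrated pair of screens and
D stays on the S-score scale (null SD sqrt(2)); the wider differential
cutoffs (+/-3.0 versus +2.0/-2.5 static) absorb that extra noise.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import (
    DIFFERENTIAL_THRESHOLDS,
    ColonyPlateSet,
    EmapValidationError,
    InteractionMatrix,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Rankit normalization
# ---------------------------------------------------------------------------

def rankit_normalize(values) -> np.ndarray:
    """Rank-based inverse-normal transform: Phi^-1((r - 0.5)/n).

    Ranks are 1-based ascending; ties receive the mean of their ranks.
    A single value maps to Phi^-1(0.5) = 0.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("rankit_normalize expects a 1-D vector")
    if values.size == 0:
        raise ValueError("rankit_normalize expects at least one value")
    if not np.all(np.isfinite(values)):
        raise ValueError("rankit_normalize requires finite input")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.5) / values.size)


# ---------------------------------------------------------------------------
# S-scores
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=None)
def variance_floor_weight(n_replicates: int) -> float:
    """Weight c such that the moderated denominator sqrt((s^2 + c*vmed)/n)
    yields unit null S variance under Gaussian replicate noise.

    With X = s^2/v ~ chi2_{n-1}/(n-1) and vmed = median(s^2) = q*v across a
    library of pairs sharing noise variance v (q = median of X), the null
    S variance is E[1/(X + c*q)]; c solves E[1/(X + c*q)] = 1.
    """
    nu = n_replicates - 1
    if nu < 1:
        raise ValueError("need at least 2 replicates")
    q = stats.chi2.median(nu) / nu
    # E[1/(X + a)] via the quantile representation: integrate over u in (0, 1)
    # at midpoints — robust where the density-weighted integrand is singular.
    u = (np.arange(200_000) + 0.5) / 200_000
    x = stats.chi2.ppf(u, nu) / nu

    def null_var(a: float) -> float:
        return float(np.mean(1.0 / (x + a)))

    a = optimize.brentq(lambda a: null_var(a) - 1.0, 1e-6, 50.0, xtol=1e-12)
    return a / q


def estimate_reference_size(plates: ColonyPlateSet, condition: str) -> float:
    """Wild-type reference colony size C0: the mean of size / (f_q * f_t).

    The mean ratio is exactly unbiased under multiplicative unit-mean colony
    noise (a median would sit below the mean of the skewed size distribution
    and shift every null S-score positive).  Interacting pairs perturb it
    only at second order: they are sparse and their effect signs are
    approximately symmetric.
    """
    k = plates.conditions.index(condition)
    fq = np.array([plates.fitness(q, condition) for q in plates.queries])
    ft = np.array([plates.fitness(t, condition) for t in plates.tests])
    expected = fq[:, None] * ft[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = plates.sizes[:, :, k, :] / expected[:, :, None]
    ratios = ratios[np.isfinite(ratios)]
    if ratios.size == 0:
        raise EmapValidationError(f"no measured colonies in condition {condition!r}")
    c0 = float(np.mean(ratios))
    if c0 <= 0:
        raise EmapValidationError("reference colony size C0 must be positive")
    return c0


def compute_sscores(
    plates: ColonyPlateSet,
    condition: str,
    c0: float | None = None,
    variance_floor: float | None = None,
    thresholds: tuple[float, float] = (2.0, -2.5),
    center: bool = True,
) -> InteractionMatrix:
    """Score every (query, test) pair in one condition.

    Parameters
    ----------
    c0
        Wild-type reference colony size.  Estimated from the data when
        omitted (:func:`estimate_reference_size`).
    variance_floor
        Additive floor on the replicate sample variance.  ``None`` (default)
        auto-calibrates it as ``c * median(s^2)`` with ``c`` from
        :func:`variance_floor_weight`; pass ``0.0`` for the plain replicate
        t-denominator sqrt(s^2/n).
    center
        Subtract the library-wide median S so the neutral bulk sits at zero
        (the usual EMAP normalization step; robust to the sparse interacting
        minority).  Disable for single-pair hand calculations.
    """
    if condition not in plates.conditions:
        raise EmapValidationError(f"condition {condition!r} not in plate set")
    if plates.n_replicates < 2:
        raise EmapValidationError("scoring requires at least 2 replicates")
    k = plates.conditions.index(condition)
    if c0 is None:
        c0 = estimate_reference_size(plates, condition)
    if c0 <= 0:
        raise EmapValidationError("C0 must be positive")

    fq = np.array([plates.fitness(q, condition) for q in plates.queries])
    ft = np.array([plates.fitness(t, condition) for t in plates.tests])
    expected = fq[:, None] * ft[None, :]

    obs = plates.sizes[:, :, k, :] / c0  # (nq, nt, nr)
    n_obs = np.sum(np.isfinite(obs), axis=2)
    complete = n_obs >= 2
    n_incomplete = int(np.sum(~complete))
    if n_incomplete:
        logger.warning(
            "condition %r: %d pairs with <2 replicates masked", condition, n_incomplete
        )
    with np.errstate(invalid="ignore"):
        mean_o = np.nanmean(np.where(np.isfinite(obs), obs, np.nan), axis=2)
        s2 = np.nanvar(np.where(np.isfinite(obs), obs, np.nan), axis=2, ddof=1)
    if variance_floor is None:
        med = float(np.nanmedian(s2[complete])) if complete.any() else 0.0
        floor = variance_floor_weight(plates.n_replicates) * med
    else:
        floor = float(variance_floor)

    with np.errstate(invalid="ignore", divide="ignore"):
        numerator = mean_o - expected
        scores = numerator / np.sqrt((s2 + floor) / n_obs)
    # observed == expected with zero replicate scatter is a perfect null, not 0/0
    scores = np.where(complete & (numerator == 0.0), 0.0, scores)
    mask = ~complete | ~np.isfinite(scores)
    scores = np.where(mask, 0.0, scores)
    if center and (~mask).any():
        scores = np.where(mask, 0.0, scores - np.median(scores[~mask]))
    return InteractionMatrix(
        queries=list(plates.queries),
        tests=list(plates.tests),
        condition=condition,
        scores=scores,
        mask=mask,
        thresholds=thresholds,
    )


# ---------------------------------------------------------------------------
# Significance calls
# ---------------------------------------------------------------------------

@dataclass
class SignificanceCalls:
    """Signed significance calls: +1 alleviating, -1 aggravating, 0 none.

    ``mask`` marks unmeasured pairs (no call, excluded from densities).
    ``scores`` retains the underlying score matrix for edge weights.
    """

    queries: list[str]
    tests: list[str]
    calls: np.ndarray
    mask: np.ndarray
    scores: np.ndarray
    mode: str
    thresholds: tuple[float, float]

    def n_positive(self) -> int:
        return int(np.sum(self.calls == 1))

    def n_negative(self) -> int:
        return int(np.sum(self.calls == -1))

    def n_significant(self) -> int:
        return self.n_positive() + self.n_negative()


MODE_THRESHOLDS = {"static": (2.0, -2.5), "differential": DIFFERENTIAL_THRESHOLDS}


def call_significant(matrix, mode: str = "static", thresholds=None) -> SignificanceCalls:
    """Threshold a score matrix into signed significance calls.

    ``matrix`` is an :class:`InteractionMatrix` or :class:`DifferentialMatrix`.
    Cutoffs default to the matrix's own thresholds when they match the mode
    convention, else to the mode defaults (static +2.0/-2.5, differential
    +/-3.0); an explicit ``thresholds`` pair overrides both.  Calls are
    inclusive: score >= positive cutoff or score <= negative cutoff.
    """
    if mode not in MODE_THRESHOLDS:
        raise ValueError(f"mode must be one of {sorted(MODE_THRESHOLDS)}, got {mode!r}")
    if thresholds is None:
        thresholds = getattr(matrix, "thresholds", None) or MODE_THRESHOLDS[mode]
    pos, neg = thresholds
    if not (pos > 0 > neg):
        raise EmapValidationError(f"thresholds must satisfy positive > 0 > negative: {thresholds}")
    calls = np.zeros(matrix.scores.shape, dtype=np.int8)
    calls[matrix.scores >= pos] = 1
    calls[matrix.scores <= neg] = -1
    calls[matrix.mask] = 0
    return SignificanceCalls(
        queries=list(matrix.queries),
        tests=list(matrix.tests),
        calls=calls,
        mask=matrix.mask.copy(),
        scores=matrix.scores.copy(),
        mode=mode,
        thresholds=(pos, neg),
    )


# ---------------------------------------------------------------------------
# Differential networks
# ---------------------------------------------------------------------------

@dataclass
class DifferentialMatrix:
    """Per-pair differential interaction scores between two conditions."""

    queries: list[str]
    tests: list[str]
    condition_pair: tuple[str, str]  # (treated, untreated)
    scores: np.ndarray  # D, single-condition S-score scale
    mask: np.ndarray
    sigma_delta: float  # robust spread of the raw difference
    thresholds: tuple[float, float] = DIFFERENTIAL_THRESHOLDS

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape


def compute_differential(
    treated: InteractionMatrix, untreated: InteractionMatrix
) -> DifferentialMatrix:
    """Subtract the untreated screen from the treated screen, pair by pair.

    The raw difference Delta = S_treated - S_untreated is standardized to
    single-condition score units, D = sqrt(2) * Delta / sigma_delta with
    sigma_delta = 1.4826 * MAD(Delta) over unmasked pairs, so that a
    condition-specific interaction of score-scale magnitude m appears at
    D ~ m.  Pairs masked in either parent stay masked.
    """
    if treated.queries != untreated.queries or treated.tests != untreated.tests:
        missing_q = set(treated.queries) ^ set(untreated.queries)
        missing_t = set(treated.tests) ^ set(untreated.tests)
        raise EmapValidationError(
            "treated/untreated axes differ; symmetric difference "
            f"queries={sorted(missing_q)} tests={sorted(missing_t)}"
        )
    mask = treated.mask | untreated.mask
    delta = treated.scores - untreated.scores
    unmasked = delta[~mask]
    if unmasked.size == 0:
        raise EmapValidationError("no shared unmasked pairs")
    sigma_delta = float(1.4826 * np.median(np.abs(unmasked - np.median(unmasked))))
    if sigma_delta == 0.0:
        # Degenerate spread (e.g. identical screens): fall back to the SD,
        # then to the raw difference so that D(X, X) is identically zero.
        sd = float(np.std(unmasked))
        scale = np.sqrt(2.0) / sd if sd > 0 else 1.0
    else:
        scale = np.sqrt(2.0) / sigma_delta
    scores = np.where(mask, 0.0, delta * scale)
    return DifferentialMatrix(
        queries=list(treated.queries),
        tests=list(treated.tests),
        condition_pair=(treated.condition, untreated.condition),
        scores=scores,
        mask=mask,
        sigma_delta=sigma_delta,
    )


# ---------------------------------------------------------------------------
# Per-query tallies
# ---------------------------------------------------------------------------

@dataclass
class QueryTally:
    """Significant-interaction counts per query, optionally rankit-normalized."""

    table: pd.DataFrame  # columns: query, n_positive, n_negative, n_total[, rankit]
    condition: str

    def counts(self, query: str) -> tuple[int, int]:
        row = self.table.loc[self.table["query"] == query]
        if row.empty:
            raise KeyError(query)
        return int(row["n_positive"].iloc[0]), int(row["n_negative"].iloc[0])


def tally_by_query(
    calls: SignificanceCalls, normalize: bool = False, condition: str = ""
) -> QueryTally:
    """Count significant positive / negative interactions per query.

    With ``normalize=True`` the total counts across queries are passed
    through :func:`rankit_normalize`, putting screens of different breadth
    on a common normal scale for cross-condition comparison.
    """
    n_pos = np.sum(calls.calls == 1, axis=1)
    n_neg = np.sum(calls.calls == -1, axis=1)
    table = pd.DataFrame(
        {
            "query": calls.queries,
            "n_positive": n_pos.astype(int),
            "n_negative": n_neg.astype(int),
            "n_total": (n_pos + n_neg).astype(int),
        }
    )
    if normalize:
        table["rankit"] = rankit_normalize(table["n_total"].to_numpy(dtype=float))
    return QueryTally(table=table, condition=condition or calls.mode)
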