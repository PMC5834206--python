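"""Synthetic EMAP generator with planted ground truth.

Emulates a screen of a query-mutant panel crossed against a test-mutant
library (defaults: 54 queries x 1536 tests, two growth conditions, four
replicate colonies per double mutant), with:

* block-structured *query modules* — all queries in a module share one
  planted interaction profile over a sparse random subset of tests;
* an optional *anti-module* whose planted profile is the sign-flipped copy
  of another module's (modelling subunits of one complex whose genetic
  signatures anti-correlate);
* *condition-specific (differential) interactions* — a fraction of each
  module's planted pairs carry their effect only in the treated condition;
* two observation layers: a score-scale layer (planted effect + Gaussian
  noise, for targeting downstream stages directly) and a colony layer
  (multiplicative fitness model with unit-mean log-normal colony noise, for
  exercising the scorer end-to-end).

All randomness flows through ``numpy.random.default_rng`` (PCG64); one seed
yields one dataset, bit-for-bit, across platforms.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .io_formats import ColonyPlateSet, InteractionMatrix, STATIC_THRESHOLDS

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class SimulationConfig:
    """Study-condition parameters of the simulated screen.

    Parameters
    ----------
    n_queries, n_tests
        Screen geometry; defaults match a 54-query panel against a
        1536-strain test library.
    conditions
        Growth-condition labels; the first is the untreated baseline.
    n_replicates
        Colonies pinned per double mutant (colony layer), default 4.
    n_modules / module_partition
        Number of planted query modules (queries split into contiguous,
        near-equal blocks), or an explicit query-index -> module-label map.
    interaction_sparsity
        Fraction pi of the test library carrying a planted interaction for
        each module (0 = null screen with no planted structure).
    effect_mean, effect_sd
        Planted interaction magnitudes are |Normal(mu, tau)| with a random
        sign per (module, test); on the S-score scale.
    differential_fraction
        Fraction delta of each module's planted pairs whose effect is
        present only in non-baseline (treated) conditions.
    noise_sd
        Additive score-scale measurement noise sigma (score layer).
    colony_noise_cv
        Coefficient of variation of the multiplicative colony-size noise
        (colony layer).  The noise is log-normal with unit mean.
    missing_fraction
        Fraction of pairs masked at random (failed pins), per condition.
    anti_module
        Optional ``(module, reference_module)``: the first module's planted
        profile is the negation of the second's.
    """

    n_queries: int = 54
    n_tests: int = 1536
    conditions: tuple[str, ...] = ("untreated", "treated")
    n_replicates: int = 4
    n_modules: int = 4
    module_partition: dict[int, str] | None = None
    interaction_sparsity: float = 0.1
    effect_mean: float = 0.0
    effect_sd: float = 5.0
    differential_fraction: float = 0.25
    noise_sd: float = 1.0
    colony_noise_cv: float = 0.15
    missing_fraction: float = 0.02
    anti_module: tuple[str, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_queries < 1 or self.n_tests < 1 or self.n_replicates < 1:
            raise ConfigError("all counts must be positive")
        if not self.conditions:
            raise ConfigError("at least one condition required")
        if not 0.0 <= self.interaction_sparsity < 1.0:
            raise ConfigError("interaction_sparsity must be in [0, 1)")
        if not 0.0 < self.differential_fraction < 1.0:
            raise ConfigError("differential_fraction must be in (0, 1)")
        if self.noise_sd <= 0 or self.colony_noise_cv <= 0:
            raise ConfigError("noise_sd and colony_noise_cv must be positive")
        if self.effect_sd < 0:
            raise ConfigError("effect_sd must be non-negative")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ConfigError("missing_fraction must be in [0, 1)")
        if self.module_partition is not None:
            if set(self.module_partition) != set(range(self.n_queries)):
                raise ConfigError("module_partition must cover every query index")
        elif self.n_modules > self.n_queries:
            raise ConfigError("more modules than queries")
        if self.anti_module is not None:
            labels = set(self.partition().values())
            mod, ref = self.anti_module
            if mod not in labels or ref not in labels or mod == ref:
                raise ConfigError(f"anti_module {self.anti_module} not two distinct module labels")

    def partition(self) -> dict[int, str]:
        """Query-index -> module-label map (contiguous near-equal blocks by default)."""
        if self.module_partition is not None:
            return dict(self.module_partition)
        bounds = np.linspace(0, self.n_queries, self.n_modules + 1).round().astype(int)
        out: dict[int, str] = {}
        for m in range(self.n_modules):
            for i in range(bounds[m], bounds[m + 1]):
                out[i] = f"M{m + 1}"
        return out

    def query_names(self) -> list[str]:
        return [f"Q{i + 1:03d}" for i in range(self.n_queries)]

    def test_names(self) -> list[str]:
        return [f"T{j + 1:04d}" for j in range(self.n_tests)]


@dataclass
class GroundTruth:
    """Planted structure of a simulated screen.

    ``epsilon`` has shape (n_queries, n_tests, n_conditions) on the S-score
    scale; it is zero for every non-planted pair, and zero in the baseline
    condition for differential-only pairs.  ``kappa`` is the epistasis ->
    fitness-multiplier calibration constant of the colony layer (None for
    the score layer).
    """

    true_module: dict[str, str]
    epsilon: np.ndarray
    differential_only: list[tuple[str, str]]
    module_supports: dict[str, np.ndarray] = field(default_factory=dict)
    kappa: float | None = None

    def labels_for(self, queries: list[str]) -> list[str]:
        return [self.true_module[q] for q in queries]


def _plant(config: SimulationConfig, rng: np.random.Generator) -> GroundTruth:
    """Draw module supports, signed effects and differential-only flags."""
    nq, nt, nc = config.n_queries, config.n_tests, len(config.conditions)
    partition = config.partition()
    queries = config.query_names()
    tests = config.test_names()
    labels = sorted(set(partition.values()))
    n_planted = int(round(config.interaction_sparsity * nt))

    profiles: dict[str, np.ndarray] = {}
    diff_flags: dict[str, np.ndarray] = {}
    supports: dict[str, np.ndarray] = {}
    anti_mod, anti_ref = config.anti_module or (None, None)
    for label in labels:
        if label == anti_mod:
            continue
        profile = np.zeros(nt)
        is_diff = np.zeros(nt, dtype=bool)
        if n_planted:
            support = rng.choice(nt, size=n_planted, replace=False)
            magnitudes = np.abs(rng.normal(config.effect_mean, config.effect_sd, n_planted))
            signs = rng.choice([-1.0, 1.0], size=n_planted)
            profile[support] = signs * magnitudes
            n_diff = int(round(config.differential_fraction * n_planted)) if nc > 1 else 0
            if n_diff:
                is_diff[rng.choice(support, size=n_diff, replace=False)] = True
            supports[label] = np.sort(support)
        else:
            supports[label] = np.array([], dtype=int)
        profiles[label] = profile
        diff_flags[label] = is_diff
    if anti_mod is not None:
        profiles[anti_mod] = -profiles[anti_ref]
        diff_flags[anti_mod] = diff_flags[anti_ref].copy()
        supports[anti_mod] = supports[anti_ref].copy()

    epsilon = np.zeros((nq, nt, nc))
    differential_only: list[tuple[str, str]] = []
    for i in range(nq):
        label = partition[i]
        profile, is_diff = profiles[label], diff_flags[label]
        for c in range(nc):
            if c == 0:
                epsilon[i, :, c] = np.where(is_diff, 0.0, profile)
            else:
                epsilon[i, :, c] = profile
        differential_only.extend((queries[i], tests[j]) for j in np.flatnonzero(is_diff))
    return GroundTruth(
        true_module={queries[i]: partition[i] for i in range(nq)},
        epsilon=epsilon,
        differential_only=differential_only,
        module_supports=supports,
    )


def simulate_scores(
    config: SimulationConfig,
) -> tuple[dict[str, InteractionMatrix], GroundTruth]:
    """Score-layer simulation: score(q, t, c) = epsilon(q, t, c) + N(0, sigma).

    Returns one :class:`InteractionMatrix` per condition (static thresholds
    attached) plus the planted :class:`GroundTruth`.  A ``missing_fraction``
    of pairs is masked at random in each condition.
    """
    rng = np.random.default_rng(config.seed)
    truth = _plant(config, rng)
    queries, tests = config.query_names(), config.test_names()
    matrices: dict[str, InteractionMatrix] = {}
    for c, cond in enumerate(config.conditions):
        scores = truth.epsilon[:, :, c] + rng.normal(
            0.0, config.noise_sd, size=(config.n_queries, config.n_tests)
        )
        mask = rng.random((config.n_queries, config.n_tests)) < config.missing_fraction
        matrices[cond] = InteractionMatrix(
            queries=list(queries),
            tests=list(tests),
            condition=cond,
            scores=np.where(mask, 0.0, scores),
            mask=mask,
            thresholds=STATIC_THRESHOLDS,
        )
    return matrices, truth


# ---------------------------------------------------------------------------
# Colony layer
# ---------------------------------------------------------------------------

#: Global wild-type colony size (arbitrary area units).
C0_DEFAULT = 1000.0


def _unit_mean_lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean exactly 1 and coefficient of variation cv."""
    s2 = np.log1p(cv**2)
    return rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=size)


def _first_order_kappa(n_replicates: int, cv: float) -> float:
    """Analytic first guess for the epistasis -> fitness multiplier slope."""
    from .scoring import variance_floor_weight
    from scipy import stats

    a = variance_floor_weight(n_replicates) * (
        stats.chi2.median(n_replicates - 1) / (n_replicates - 1)
    )
    return cv * np.sqrt((1.0 + a) / n_replicates)


@functools.lru_cache(maxsize=None)
def calibrate_kappa(n_replicates: int, cv: float, noise_sd: float = 1.0) -> float:
    """Calibrate kappa so the scorer recovers planted epsilon in expectation.

    One internal seeded simulation: plant a grid of known effects through
    the colony layer with the first-order kappa, score it, and correct
    kappa by the inverse of the measured recovery slope.
    """
    from .scoring import compute_sscores

    kappa0 = _first_order_kappa(n_replicates, cv)
    rng = np.random.default_rng(987654321)
    nq, nt = 6, 600
    eps = np.zeros((nq, nt))
    grid = np.array([-6.0, -3.0, 3.0, 6.0])
    planted = rng.choice(nq * nt, size=nq * nt // 10, replace=False)
    eps.flat[planted] = rng.choice(grid, size=planted.size)
    g = np.clip(1.0 + kappa0 * eps, 0.01, None)
    sizes = (
        C0_DEFAULT
        * g[:, :, None]
        * _unit_mean_lognormal(rng, cv, (nq, nt, n_replicates))
    )
    plates = ColonyPlateSet(
        queries=[f"q{i}" for i in range(nq)],
        tests=[f"t{j}" for j in range(nt)],
        conditions=["cal"],
        sizes=sizes[:, :, None, :],
        n_replicates=n_replicates,
        single_fitness={
            **{(f"q{i}", "cal"): 1.0 for i in range(nq)},
            **{(f"t{j}", "cal"): 1.0 for j in range(nt)},
        },
    )
    scored = compute_sscores(plates, "cal", c0=C0_DEFAULT)
    s, e = scored.scores.ravel(), eps.ravel()
    slope = float(np.sum(s * e) / np.sum(e * e))
    if not 0.05 < slope < 20.0:
        raise RuntimeError(f"kappa calibration failed: slope {slope}")
    kappa = kappa0 / slope * (noise_sd if noise_sd > 0 else 1.0)
    return float(kappa)


def simulate_colonies(config: SimulationConfig) -> tuple[ColonyPlateSet, GroundTruth]:
    """Colony-layer simulation.

    Single-mutant fitnesses f are drawn once per strain from a Normal(1, 0.1)
    truncated to (0, inf) and shared across conditions.  The expected
    double-mutant size is C0 * f_q * f_t * g(eps) with g(eps) = 1 + kappa*eps
    (clipped below at 0.01); replicate sizes multiply that expectation by
    unit-mean log-normal noise with the configured CV.  kappa is the cached
    internal calibration making the scorer recover eps in expectation.
    """
    rng = np.random.default_rng(config.seed)
    truth = _plant(config, rng)
    truth.kappa = calibrate_kappa(config.n_replicates, config.colony_noise_cv, config.noise_sd)
    queries, tests = config.query_names(), config.test_names()

    def trunc_normal(n: int) -> np.ndarray:
        out = rng.normal(1.0, 0.1, n)
        while np.any(out <= 0):  # resample the rare non-positive draws
            bad = out <= 0
            out[bad] = rng.normal(1.0, 0.1, bad.sum())
        return out

    fq, ft = trunc_normal(config.n_queries), trunc_normal(config.n_tests)
    nc, nr = len(config.conditions), config.n_replicates
    g = np.clip(1.0 + truth.kappa * truth.epsilon, 0.01, None)  # (nq, nt, nc)
    expected = C0_DEFAULT * fq[:, None, None] * ft[None, :, None] * g
    noise = _unit_mean_lognormal(
        rng, config.colony_noise_cv, (config.n_queries, config.n_tests, nc, nr)
    )
    sizes = expected[:, :, :, None] * noise
    if config.missing_fraction > 0:
        drop = rng.random((config.n_queries, config.n_tests, nc)) < config.missing_fraction
        sizes[drop] = np.nan

    single_fitness: dict[tuple[str, str], float] = {}
    for cond in config.conditions:
        single_fitness.update({(q, cond): float(f) for q, f in zip(queries, fq)})
        single_fitness.update({(t, cond): float(f) for t, f in zip(tests, ft)})
    plates = ColonyPlateSet(
        queries=list(queries),
        tests=list(tests),
        conditions=list(config.conditions),
        sizes=sizes,
        n_replicates=nr,
        single_fitness=single_fitness,
    )
    return plates, truth


# ---------------------------------------------------------------------------
# Benchmark battery
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkCase:
    """One generator configuration plus the recovery metric it is built to test."""

    name: str
    config: SimulationConfig
    expectation: dict


def make_benchmark_suite(seed: int) -> list[BenchmarkCase]:
    """Fixed battery of generator configurations with known expected recovery.

    (i)   four well-separated modules (effect_sd / noise_sd = 5);
    (ii)  two modules, the second the anti-module of the first;
    (iii) null screen with no planted structure;
    (iv)  differential screen, half the planted pairs treated-only with
          score-scale effect magnitudes centred at 6.
    """
    base = dict(
        n_queries=54,
        n_tests=1536,
        n_replicates=4,
        interaction_sparsity=0.1,
        effect_mean=0.0,
        effect_sd=5.0,
        noise_sd=1.0,
        seed=seed,
    )
    easy = SimulationConfig(**base, conditions=("untreated",), n_modules=4)
    anti = SimulationConfig(
        **base, conditions=("untreated",), n_modules=2, anti_module=("M2", "M1")
    )
    null = replace(easy, interaction_sparsity=0.0, n_modules=1)
    diff = SimulationConfig(
        **{**base, "effect_mean": 6.0, "effect_sd": 1.0},
        conditions=("untreated", "treated"),
        n_modules=4,
        differential_fraction=0.5,
    )
    return [
        BenchmarkCase("four_module_easy", easy, {"select_k": 4, "min_ari": 0.9}),
        BenchmarkCase("anti_module", anti, {"select_k": 2, "max_anti_corr": -0.6}),
        BenchmarkCase("null", null, {"max_silhouette": 0.25}),
        BenchmarkCase("differential", diff, {"min_recovery": 0.9, "abs_d_cutoff": 3.0}),
    ]
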