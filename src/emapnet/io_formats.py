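"""Typed containers and strict TSV/GMT readers and writers for EMAP tables.

Everything downstream of this module operates on in-memory structures:
:class:`InteractionMatrix` (queries x tests S-scores for one growth
condition), :class:`ColonyPlateSet` (replicate colony sizes plus parental
single-mutant fitness), and :class:`GeneSetCollection` (pathway / GO
membership lists).

Format conventions
------------------
* All tables are tab-separated; ``NA`` is the sole missing token.
* Score matrices carry their condition and significance thresholds in
  ``#``-prefixed header comment lines, so one file is self-describing.
* Identifiers are case-preserved and matched case-sensitively (yeast
  gene/ORF conventions distinguish case meaningfully).
* Parsers never silently drop data: every collapsed or skipped record is
  logged with its location.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Static-condition significance cutoffs (alleviating >= 2.0, aggravating <= -2.5).
STATIC_THRESHOLDS = (2.0, -2.5)
#: Differential-condition cutoffs (|D| >= 3.0).
DIFFERENTIAL_THRESHOLDS = (3.0, -3.0)

MISSING_TOKEN = "NA"


class EmapValidationError(ValueError):
    """Raised when a table violates the structural invariants of its type."""


class EmapParseError(ValueError):
    """Raised when a file cannot be parsed; the message names the location."""


def _check_unique(identifiers, what: str) -> None:
    seen: set[str] = set()
    for ident in identifiers:
        if ident in seen:
            raise EmapValidationError(f"duplicate {what} identifier: {ident!r}")
        seen.add(ident)


@dataclass
class InteractionMatrix:
    """S-scores for one condition, queries in rows and tests in columns.

    ``mask`` is True where a pair was not measured; masked entries are
    excluded from every downstream statistic. ``thresholds`` is the pair
    ``(positive_cutoff, negative_cutoff)`` used to call significant
    alleviating / aggravating interactions.
    """

    queries: list[str]
    tests: list[str]
    condition: str
    scores: np.ndarray
    mask: np.ndarray
    thresholds: tuple[float, float] = STATIC_THRESHOLDS

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.validate()

    def validate(self) -> None:
        nq, nt = len(self.queries), len(self.tests)
        if nq == 0 or nt == 0:
            raise EmapValidationError("matrix must have at least one query and one test")
        if self.scores.shape != (nq, nt):
            raise EmapValidationError(
                f"score matrix shape {self.scores.shape} does not match "
                f"{nq} queries x {nt} tests"
            )
        if self.mask.shape != self.scores.shape:
            raise EmapValidationError("mask shape does not match score matrix")
        _check_unique(self.queries, "query")
        _check_unique(self.tests, "test")
        pos, neg = self.thresholds
        if not (pos > 0 > neg):
            raise EmapValidationError(
                f"thresholds must satisfy positive > 0 > negative, got {self.thresholds}"
            )
        if not np.all(np.isfinite(self.scores[~self.mask])):
            raise EmapValidationError("unmasked scores must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape

    def query_index(self, names) -> np.ndarray:
        return _index_of(self.queries, names, "query")

    def test_index(self, names) -> np.ndarray:
        return _index_of(self.tests, names, "test")


def _index_of(axis: list[str], names, what: str) -> np.ndarray:
    lookup = {name: i for i, name in enumerate(axis)}
    missing = [n for n in names if n not in lookup]
    if missing:
        raise EmapValidationError(f"unknown {what} identifiers: {missing}")
    return np.array([lookup[n] for n in names], dtype=int)


@dataclass
class ColonyPlateSet:
    """Replicate double-mutant colony sizes plus parental fitness.

    ``sizes`` has shape (n_queries, n_tests, n_conditions, n_replicates);
    missing replicates are NaN.  ``single_fitness`` maps
    ``(strain, condition)`` to relative fitness (wild type = 1).
    """

    queries: list[str]
    tests: list[str]
    conditions: list[str]
    sizes: np.ndarray
    n_replicates: int
    single_fitness: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.validate()

    def validate(self) -> None:
        _check_unique(self.queries, "query")
        _check_unique(self.tests, "test")
        _check_unique(self.conditions, "condition")
        expected = (
            len(self.queries),
            len(self.tests),
            len(self.conditions),
            self.n_replicates,
        )
        if self.sizes.shape != expected:
            raise EmapValidationError(
                f"sizes shape {self.sizes.shape} does not match {expected}"
            )
        if self.n_replicates < 1:
            raise EmapValidationError("n_replicates must be positive")
        finite = self.sizes[np.isfinite(self.sizes)]
        if finite.size and finite.min() < 0:
            raise EmapValidationError("colony sizes must be non-negative")
        for (strain, cond), f in self.single_fitness.items():
            if not (math.isfinite(f) and f >= 0):
                raise EmapValidationError(
                    f"single fitness for ({strain!r}, {cond!r}) must be >= 0, got {f}"
                )

    def fitness(self, strain: str, condition: str) -> float:
        try:
            return self.single_fitness[(strain, condition)]
        except KeyError:
            raise EmapValidationError(
                f"no single-mutant fitness for strain {strain!r} in condition {condition!r}"
            ) from None


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways, complexes, GO terms)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise EmapValidationError(f"gene set {name!r} is empty")
            _check_unique(members, f"member of set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# Score matrices
# ---------------------------------------------------------------------------

def read_score_matrix(path, condition: str | None = None) -> InteractionMatrix:
    """Read a queries x tests S-score TSV.

    Layout: optional ``#``-prefixed header comments (``# condition: ...``,
    ``# thresholds: <pos> <neg>``), then a header row of test identifiers
    (first cell empty or a corner label), then one row per query.  Cells are
    reals or ``NA``.  An explicit ``condition`` argument overrides the header.
    """
    header_condition = None
    thresholds = STATIC_THRESHOLDS
    rows: list[tuple[int, list[str]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("condition:"):
                    header_condition = body.split(":", 1)[1].strip()
                elif body.lower().startswith("thresholds:"):
                    parts = body.split(":", 1)[1].split()
                    if len(parts) != 2:
                        raise EmapParseError(
                            f"{path}:{lineno}: malformed thresholds header {line!r}"
                        )
                    thresholds = (float(parts[0]), float(parts[1]))
                continue
            rows.append((lineno, line.split("\t")))
    if not rows:
        raise EmapParseError(f"{path}: no data rows")
    header_line, header = rows[0]
    tests = header[1:]
    if not tests:
        raise EmapParseError(f"{path}:{header_line}: header row has no test columns")
    queries: list[str] = []
    scores = np.zeros((len(rows) - 1, len(tests)))
    mask = np.zeros_like(scores, dtype=bool)
    for i, (lineno, cells) in enumerate(rows[1:]):
        if len(cells) != len(tests) + 1:
            raise EmapParseError(
                f"{path}:{lineno}: row {cells[0]!r} has {len(cells) - 1} cells, "
                f"expected {len(tests)}"
            )
        queries.append(cells[0])
        for j, cell in enumerate(cells[1:]):
            if cell == MISSING_TOKEN:
                mask[i, j] = True
            else:
                try:
                    scores[i, j] = float(cell)
                except ValueError:
                    raise EmapParseError(
                        f"{path}:{lineno}: cell {cell!r} is neither a real nor "
                        f"{MISSING_TOKEN!r}"
                    ) from None
    return InteractionMatrix(
        queries=queries,
        tests=tests,
        condition=condition or header_condition or "unknown",
        scores=scores,
        mask=mask,
        thresholds=thresholds,
    )


def write_score_matrix(matrix: InteractionMatrix, path) -> str:
    """Write a matrix as TSV re-readable by :func:`read_score_matrix`.

    Masked cells are serialized as ``NA``; unmasked values use 17 significant
    digits so the write/read round trip is bit-exact.
    """
    matrix.validate()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# condition: {matrix.condition}\n")
        fh.write(f"# thresholds: {matrix.thresholds[0]:g} {matrix.thresholds[1]:g}\n")
        fh.write("\t" + "\t".join(matrix.tests) + "\n")
        for i, q in enumerate(matrix.queries):
            cells = [
                MISSING_TOKEN if matrix.mask[i, j] else format(matrix.scores[i, j], ".17g")
                for j in range(len(matrix.tests))
            ]
            fh.write(q + "\t" + "\t".join(cells) + "\n")
    return str(path)


# ---------------------------------------------------------------------------
# GMT gene sets and annotation tables
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read a standard GMT file: name, description, members, tab-separated.

    Duplicate members within a line are collapsed (order preserved) with a
    logged warning.  An empty file yields an empty collection.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise EmapParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name, desc, members = fields[0], fields[1], fields[2:]
            unique = list(dict.fromkeys(m for m in members if m))
            if len(unique) < len([m for m in members if m]):
                logger.warning(
                    "%s:%d: set %r has duplicate members; collapsed to %d unique",
                    path, lineno, name, len(unique),
                )
            if name in sets:
                raise EmapParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> str:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")
    return str(path)


def read_annotation_table(path) -> GeneSetCollection:
    """Read a two-column gene<TAB>term table into term -> member sets."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise EmapParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}"
                )
            gene, term = fields
            members = sets.setdefault(term, [])
            if gene in members:
                logger.warning("%s:%d: duplicate annotation %r -> %r", path, lineno, gene, term)
            else:
                members.append(gene)
    return GeneSetCollection(sets=sets)


# ---------------------------------------------------------------------------
# Colony tables
# ---------------------------------------------------------------------------

COLONY_COLUMNS = ("query", "test", "condition", "replicate", "size")


def read_colony_tables(colony_path, fitness_path) -> ColonyPlateSet:
    """Assemble a :class:`ColonyPlateSet` from two long-format TSVs.

    ``colony_path`` has columns query, test, condition, replicate (1-based),
    size.  ``fitness_path`` has columns strain, condition, fitness.  Pairs
    with fewer recorded replicates than the maximum are flagged missing
    (NaN) with a logged warning.
    """
    import pandas as pd

    colonies = pd.read_csv(colony_path, sep="\t", comment="#", float_precision="round_trip")
    missing_cols = [c for c in COLONY_COLUMNS if c not in colonies.columns]
    if missing_cols:
        raise EmapParseError(f"{colony_path}: missing columns {missing_cols}")
    neg = colonies[colonies["size"] < 0]
    if len(neg):
        row = neg.iloc[0]
        raise EmapValidationError(
            f"{colony_path}: negative colony size for "
            f"({row['query']!r}, {row['test']!r}, {row['condition']!r}, "
            f"replicate {row['replicate']})"
        )
    queries = list(dict.fromkeys(colonies["query"].astype(str)))
    tests = list(dict.fromkeys(colonies["test"].astype(str)))
    conditions = list(dict.fromkeys(colonies["condition"].astype(str)))
    n_replicates = int(colonies["replicate"].max())
    qi = {q: i for i, q in enumerate(queries)}
    ti = {t: i for i, t in enumerate(tests)}
    ci = {c: i for i, c in enumerate(conditions)}
    sizes = np.full((len(queries), len(tests), len(conditions), n_replicates), np.nan)
    for row in colonies.itertuples(index=False):
        r = int(row.replicate) - 1
        if not 0 <= r < n_replicates:
            raise EmapParseError(f"{colony_path}: replicate index {row.replicate} out of range")
        sizes[qi[str(row.query)], ti[str(row.test)], ci[str(row.condition)], r] = row.size
    n_incomplete = int(
        ((~np.isnan(sizes)).sum(axis=3) % n_replicates != 0).sum()
    )
    if n_incomplete:
        logger.warning(
            "%s: %d pairs have fewer than %d replicates; flagged missing",
            colony_path, n_incomplete, n_replicates,
        )

    fitness = pd.read_csv(fitness_path, sep="\t", comment="#", float_precision="round_trip")
    for col in ("strain", "condition", "fitness"):
        if col not in fitness.columns:
            raise EmapParseError(f"{fitness_path}: missing column {col!r}")
    single_fitness = {
        (str(row.strain), str(row.condition)): float(row.fitness)
        for row in fitness.itertuples(index=False)
    }
    return ColonyPlateSet(
        queries=queries,
        tests=tests,
        conditions=conditions,
        sizes=sizes,
        n_replicates=n_replicates,
        single_fitness=single_fitness,
    )


def write_colony_tables(plates: ColonyPlateSet, colony_path, fitness_path) -> tuple[str, str]:
    """Serialize a ColonyPlateSet to the long-format TSVs read_colony_tables expects."""
    with open(colony_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(COLONY_COLUMNS) + "\n")
        for i, q in enumerate(plates.queries):
            for j, t in enumerate(plates.tests):
                for k, c in enumerate(plates.conditions):
                    for r in range(plates.n_replicates):
                        size = plates.sizes[i, j, k, r]
                        if np.isnan(size):
                            continue
                        fh.write(f"{q}\t{t}\t{c}\t{r + 1}\t{format(size, '.17g')}\n")
    with open(fitness_path, "w", encoding="utf-8") as fh:
        fh.write("strain\tcondition\tfitness\n")
        for (strain, cond), f in plates.single_fitness.items():
            fh.write(f"{strain}\t{cond}\t{format(f, '.17g')}\n")
    return str(colony_path), str(fitness_path)
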