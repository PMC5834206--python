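"""End-to-end pipeline: simulate/score -> differential -> tallies -> modules
-> density tests -> enrichment, driven by one YAML config.

Every stage is a pure function of its declared inputs plus an explicit seed
(no global RNG), so a rerun with an identical config reproduces every
output byte-for-byte; the :class:`RunManifest` records a config snapshot,
package version, seeds and a sha256 checksum for each output, and stages
whose outputs already match their recorded checksums are skipped on rerun
(resume semantics).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .io_formats import (
    GeneSetCollection,
    write_colony_tables,
    write_gmt,
    write_score_matrix,
)
from .modules import correlate_profiles, kmeans_modules, select_k
from .netstats import density_randomization_test, enrichment_table, hypergeometric_enrichment
from .scoring import call_significant, compute_differential, compute_sscores, tally_by_query
from .synthetic import ConfigError, SimulationConfig, simulate_colonies, simulate_scores

logger = logging.getLogger(__name__)

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}


class ConfigValidationError(ValueError):
    """Raised by run_pipeline when the config fails validation."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid config:\n" + "\n".join(f"  - {e}" for e in errors))


def validate_config(config_path) -> list[str]:
    """Validate a pipeline config, returning *all* errors (empty list = ok)."""
    errors: list[str] = []
    try:
        with open(config_path, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
    except (OSError, yaml.YAMLError) as exc:
        return [f"cannot read config: {exc}"]
    if not isinstance(cfg, dict):
        return ["config root must be a mapping"]

    if "seed" not in cfg:
        errors.append("missing field: seed")
    elif not isinstance(cfg["seed"], int):
        errors.append("seed: must be an integer")

    sim = cfg.get("simulation", {})
    if not isinstance(sim, dict):
        errors.append("simulation: must be a mapping")
        sim = {}
    layer = sim.get("layer", "scores")
    if layer not in ("scores", "colonies"):
        errors.append(f"simulation.layer: must be 'scores' or 'colonies', got {layer!r}")
    unknown = set(sim) - _SIM_FIELDS - {"layer"}
    if unknown:
        errors.append(f"simulation: unknown fields {sorted(unknown)}")
    sim_kwargs = {k: v for k, v in sim.items() if k in _SIM_FIELDS}
    if "conditions" in sim_kwargs:
        sim_kwargs["conditions"] = tuple(sim_kwargs["conditions"])
    if "anti_module" in sim_kwargs and sim_kwargs["anti_module"] is not None:
        sim_kwargs["anti_module"] = tuple(sim_kwargs["anti_module"])
    try:
        SimulationConfig(seed=int(cfg.get("seed", 0) or 0), **sim_kwargs)
    except (ConfigError, TypeError, ValueError) as exc:
        errors.append(f"simulation: {exc}")

    mods = cfg.get("modules", {})
    if isinstance(mods, dict):
        k = mods.get("k", "auto")
        if k != "auto" and not isinstance(k, int):
            errors.append("modules.k: must be 'auto' or an integer")
    else:
        errors.append("modules: must be a mapping")

    dens = cfg.get("density_test", {})
    if isinstance(dens, dict):
        n_perm = dens.get("n_permutations", 100_000)
        if not isinstance(n_perm, int) or n_perm < 1:
            errors.append("density_test.n_permutations: must be a positive integer")
    else:
        errors.append("density_test: must be a mapping")
    return errors


@dataclass
class RunManifest:
    """Record of one pipeline run: config, version, seeds, output checksums."""

    config: dict
    version: str
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    stages: list[dict] = field(default_factory=list)
    completed: bool = False

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_previous(manifest_path: Path) -> dict[str, str]:
    if not manifest_path.exists():
        return {}
    try:
        prev = json.loads(manifest_path.read_text())
        return prev.get("outputs", {}) if prev.get("completed") else {}
    except (json.JSONDecodeError, OSError):
        return {}


def run_pipeline(config_path, out_dir=None) -> RunManifest:
    """Execute all stages in dependency order; returns the run manifest.

    A stage is skipped when every one of its output files already exists
    with the checksum recorded by a previous completed run of the same
    config (resume semantics).
    """
    errors = validate_config(config_path)
    if errors:
        raise ConfigValidationError(errors)
    with open(config_path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    out = Path(out_dir or cfg.get("out_dir", "emapnet_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    sim_block = dict(cfg.get("simulation", {}))
    layer = sim_block.pop("layer", "scores")
    sim_kwargs = {k: v for k, v in sim_block.items() if k in _SIM_FIELDS}
    if "conditions" in sim_kwargs:
        sim_kwargs["conditions"] = tuple(sim_kwargs["conditions"])
    if "anti_module" in sim_kwargs and sim_kwargs["anti_module"] is not None:
        sim_kwargs["anti_module"] = tuple(sim_kwargs["anti_module"])
    sim_config = SimulationConfig(seed=seed, **sim_kwargs)

    manifest = RunManifest(config=cfg, version=__version__, seed=seed)
    manifest_path = out / "manifest.json"
    previous = _load_previous(manifest_path)

    def stage_done(paths: list[Path]) -> bool:
        return all(
            p.exists() and previous.get(str(p)) == _sha256(p) for p in paths
        )

    def record(stage: str, paths: list[Path], skipped: bool) -> None:
        for p in paths:
            manifest.outputs[str(p)] = _sha256(p)
        manifest.stages.append(
            {"stage": stage, "outputs": [str(p) for p in paths],
             "skipped": skipped, "timestamp": time.time()}
        )
        logger.info("stage %s %s (%d outputs)", stage,
                    "skipped (up to date)" if skipped else "completed", len(paths))

    conditions = list(sim_config.conditions)

    # --- simulate + score ---------------------------------------------------
    score_paths = [out / f"scores_{c}.tsv" for c in conditions]
    truth_path = out / "ground_truth_modules.tsv"
    gmt_path = out / "module_gene_sets.gmt"
    sim_outputs = score_paths + [truth_path, gmt_path]
    if stage_done(sim_outputs):
        record("simulate", sim_outputs, skipped=True)
        from .io_formats import read_score_matrix

        matrices = {c: read_score_matrix(p, condition=c) for c, p in zip(conditions, score_paths)}
        truth = None
    else:
        if layer == "colonies":
            plates, truth = simulate_colonies(sim_config)
            colony_paths = [out / "colonies.tsv", out / "single_fitness.tsv"]
            write_colony_tables(plates, *colony_paths)
            sim_outputs = sim_outputs + colony_paths
            matrices = {c: compute_sscores(plates, c) for c in conditions}
        else:
            matrices, truth = simulate_scores(sim_config)
        for c, p in zip(conditions, score_paths):
            write_score_matrix(matrices[c], p)
        with open(truth_path, "w", encoding="utf-8") as fh:
            fh.write("query\tmodule\n")
            for q, m in truth.true_module.items():
                fh.write(f"{q}\t{m}\n")
        tests = sim_config.test_names()
        sets = {
            label: [tests[j] for j in support]
            for label, support in truth.module_supports.items()
            if len(support)
        }
        if sets:
            write_gmt(GeneSetCollection(sets=sets), gmt_path)
        else:  # null screen: no planted sets, keep a placeholder set of all tests
            write_gmt(GeneSetCollection(sets={"all_tests": tests}), gmt_path)
        record("simulate", sim_outputs, skipped=False)

    baseline = conditions[0]

    # --- differential -------------------------------------------------------
    diff = None
    diff_path = out / "differential.tsv"
    if len(conditions) >= 2:
        diff = compute_differential(matrices[conditions[1]], matrices[baseline])
        from .io_formats import InteractionMatrix

        diff_as_matrix = InteractionMatrix(
            queries=diff.queries, tests=diff.tests,
            condition=f"{conditions[1]}-minus-{baseline}",
            scores=diff.scores, mask=diff.mask, thresholds=diff.thresholds,
        )
        if stage_done([diff_path]):
            record("differential", [diff_path], skipped=True)
        else:
            write_score_matrix(diff_as_matrix, diff_path)
            record("differential", [diff_path], skipped=False)

    # --- significance calls + tallies --------------------------------------
    tally_paths = []
    calls_by_condition = {}
    for c in conditions:
        calls = call_significant(matrices[c], mode="static")
        calls_by_condition[c] = calls
        tally = tally_by_query(calls, normalize=True, condition=c)
        p = out / f"tally_{c}.tsv"
        tally.table.to_csv(p, sep="\t", index=False)
        tally_paths.append(p)
    if diff is not None:
        diff_calls = call_significant(diff, mode="differential")
        p = out / "tally_differential.tsv"
        tally_by_query(diff_calls, normalize=True, condition="differential").table.to_csv(
            p, sep="\t", index=False
        )
        tally_paths.append(p)
    record("tally", tally_paths, skipped=False)

    # --- modules ------------------------------------------------------------
    mods_cfg = cfg.get("modules", {}) or {}
    corr = correlate_profiles(matrices[baseline])
    k_setting = mods_cfg.get("k", "auto")
    k_max = int(mods_cfg.get("k_max", 8))
    if k_setting == "auto":
        assignment = select_k(corr, k_range=range(1, k_max + 1), seed=seed)
    else:
        assignment = kmeans_modules(corr, int(k_setting), seed=seed)
    module_path = out / "modules.tsv"
    with open(module_path, "w", encoding="utf-8") as fh:
        fh.write(f"# k: {assignment.k}\n")
        if assignment.notes:
            fh.write(f"# notes: {'; '.join(assignment.notes)}\n")
        fh.write("query\tmodule\n")
        for q in corr.queries:
            fh.write(f"{q}\t{assignment.labels[q]}\n")
    module_outputs = [module_path]
    if assignment.diagnostics is not None:
        diag_path = out / "module_diagnostics.tsv"
        assignment.diagnostics.to_csv(diag_path, sep="\t", index=False)
        module_outputs.append(diag_path)
    record("modules", module_outputs, skipped=False)

    # --- density test -------------------------------------------------------
    dens_cfg = cfg.get("density_test", {}) or {}
    from .io_formats import read_gmt

    gene_sets = read_gmt(gmt_path)
    target_set = dens_cfg.get("gene_set") or next(iter(gene_sets.sets))
    module_label = dens_cfg.get("module") or sorted(set(assignment.labels.values()))[0]
    query_set = [q for q in corr.queries if assignment.labels[q] == module_label]
    test_set = [t for t in gene_sets[target_set] if t in matrices[baseline].tests]
    density_path = out / "density_test.tsv"
    result = density_randomization_test(
        calls_by_condition[baseline],
        query_set,
        test_set,
        n_permutations=int(dens_cfg.get("n_permutations", 100_000)),
        seed=seed,
        direction=dens_cfg.get("direction", "all"),
    )
    import pandas as pd

    pd.DataFrame(
        [{
            "condition": baseline, "module": module_label, "gene_set": target_set,
            "observed_density": result.observed_density, "p_value": result.p_value,
            "null_mean": result.null_mean, "null_sd": result.null_sd,
            "n_permutations": result.n_permutations, "seed": result.seed,
            "direction": result.direction,
        }]
    ).to_csv(density_path, sep="\t", index=False)
    record("density_test", [density_path], skipped=False)

    # --- enrichment ---------------------------------------------------------
    calls = calls_by_condition[baseline]
    hit_mask = (calls.calls != 0).any(axis=0)
    hits = [t for t, h in zip(calls.tests, hit_mask) if h]
    enrich_path = out / "enrichment.tsv"
    if hits:
        results = hypergeometric_enrichment(hits, gene_sets, background=calls.tests)
        enrichment_table(results).to_csv(enrich_path, sep="\t", index=False)
    else:
        enrich_path.write_text("term\tterm_size\toverlap\tp_value\tadjusted_p\n")
    record("enrichment", [enrich_path], skipped=False)

    manifest.completed = True
    manifest_path.write_text(manifest.to_json())
    manifest.outputs[str(manifest_path)] = _sha256(manifest_path)
    return manifest
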