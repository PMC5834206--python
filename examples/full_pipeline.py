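"""Run the whole analysis from one YAML config: simulate -> score ->
differential -> tallies -> modules -> density test -> enrichment.

Every stage takes an explicit seed, outputs are TSV with checksums recorded
in a manifest, and rerunning the same config reproduces every file
byte-for-byte (already-valid stages are skipped).
"""

import tempfile
from pathlib import Path

import yaml

from emapnet import run_pipeline

config = {
    "seed": 7,
    "simulation": {
        "n_queries": 54,
        "n_tests": 1536,
        "conditions": ["untreated", "treated"],
        "n_modules": 4,
        "layer": "scores",
    },
    "modules": {"k": "auto", "k_max": 8},
    "density_test": {"n_permutations": 20000},
}

workdir = Path(tempfile.mkdtemp(prefix="emapnet_demo_"))
config_path = workdir / "run.yaml"
config_path.write_text(yaml.safe_dump(config))

manifest = run_pipeline(config_path, out_dir=workdir / "out")
print(f"pipeline completed {len(manifest.stages)} stages -> {workdir / 'out'}")
for stage in manifest.stages:
    print(f"  {stage['stage']}: {len(stage['outputs'])} output(s)"
          + ("  [skipped: up to date]" if stage["skipped"] else ""))

k_line = (workdir / "out" / "modules.tsv").read_text().splitlines()[0]
print(f"\ndetected module count: {k_line.lstrip('# ')} "
      f"(the config planted 4 query modules)")
print(f"manifest with per-file sha256 checksums: {workdir / 'out' / 'manifest.json'}")
print("\nrerun this script with the same seed and every TSV checksum matches -")
print("the manifest is the reproducibility contract of the pipeline.")
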