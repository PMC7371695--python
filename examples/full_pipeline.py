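"""Config-driven end-to-end run on simulated inputs with a manifest.

Writes a YAML run config covering all four stages, executes it twice, and
shows that the output checksums are reproducible.
"""

import tempfile
from pathlib import Path

import yaml

from pol3kit.pipeline import run_pipeline, validate_config

workdir = Path(tempfile.mkdtemp(prefix="pol3_run_"))
config_path = workdir / "run.yaml"
config_path.write_text(yaml.safe_dump({
    "output_dir": str(workdir / "out"),
    "seed": 7,
    "chip": {"simulate": {"n_loci": 500, "n_reps": 2}},
    "rnaseq": {"simulate": {"n_genes": 4000}},
    "ribo": {"simulate": {"n_genes": 2000}},
    "enrich": {},
}))

config = validate_config(config_path)
m1 = run_pipeline(config)
m2 = run_pipeline(config)

for stage, record in m1.stages.items():
    stable = record["outputs"] == m2.stages[stage]["outputs"]
    print(f"{stage:8s} {len(record['outputs'])} outputs in {record['seconds']:.2f}s, "
          f"re-run checksums identical: {stable}")
print(f"outputs and manifest.json under {workdir / 'out'}")
# Identical config + seed reproduce byte-identical outputs; the manifest
# records the config hash and SHA-256 of every file for provenance.
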