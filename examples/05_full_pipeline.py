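"""Run the whole pipeline (generate -> train -> extract -> reduce -> rsa ->
report) at desk scale and list the report artifacts.

Equivalent CLI invocation::

    visfill all --seed 7 --out scratch/demo_run
"""

from pathlib import Path

from visfill.pipeline import PipelineConfig, run_stage, run_sweep

cfg = PipelineConfig.desk_profile(out_dir="scratch/demo_run", seed=7,
                                  n_subjects=6, n_splits=20)
for stage in ("generate", "train", "extract", "reduce", "rsa"):
    run_stage(stage, cfg)
run_sweep(cfg, grid=(4, 8, 16))   # optional: similarity vs component count
run_stage("report", cfg)

rep = Path(cfg.out_dir) / "report"
print("report artifacts:")
for p in sorted(rep.iterdir()):
    print(f"  {p}")
print(f"\nfull per-subject tau table: {cfg.out_dir}/rsa_table.tsv")
print(f"manifest with per-stage seeds and digests: {cfg.out_dir}/run_manifest.json")
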