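"""Run all nine pipeline stages from one config and inspect the manifest.

simulate -> preprocess -> train -> portray -> diffexp -> spots -> gsz ->
phenomap -> project, writing TSV/PNG/JSON outputs plus manifest.json.
The same config works through the CLI: `somportray run --config cfg.yaml`.
"""

from somportray import run_pipeline

config = {
    "seed": 7,
    "simulate": {
        "n_genes": 200,
        "group_sizes": {
            "L1": {"gBRCA1": 4, "sBRCA1": 3, "gBRCA2": 3, "sBRCA2": 2, "noBRCA": 8},
            "L2": {"gBRCA1": 4, "sBRCA1": 3, "gBRCA2": 3, "sBRCA2": 2, "noBRCA": 8},
        },
        "modules": [
            {"module_id": "M1", "n_genes": 30, "target_group": "gBRCA1", "effect": 1.0},
            {"module_id": "M2", "n_genes": 30, "target_group": "gBRCA2", "effect": 1.0},
        ],
        "phenotypes": [
            {"name": "aneuploidy_score", "kind": "numeric",
             "coupled_module": "M1", "coupling_strength": 2.0, "noise_sd": 0.5},
        ],
    },
    "som": {"grid_rows": 9, "grid_cols": 9, "epochs": 60},
    "spots": {"quantile": 0.85},
}

manifest = run_pipeline(config, "example_output/full_run")
print(f"completed {len(manifest.stages)} stages:")
for name, info in manifest.stages.items():
    print(f"  {name:10s} {info['seconds']:6.2f} s  {len(info['outputs'])} output(s)")
print("outputs and manifest.json under example_output/full_run/")
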