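"""End-to-end pipeline orchestration with a machine-readable run manifest.

A single YAML config drives nine stages: simulate (or ingest) ->
preprocess -> train -> portray -> diffexp -> spots -> gsz -> phenomap ->
project. Each stage writes plain-text outputs under the run directory and
is recorded in the manifest (config snapshot, input checksums, output
paths, seed, version, timestamps). A failing stage aborts the run with
the stage name. Given identical inputs, config and seed, all numeric
outputs are bit-identical across reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__ as _pkg_version
from .data_core import (
    GROUPS,
    DataError,
    build_multilayer,
    make_layer,
    read_annotations,
    read_count_matrix,
    write_annotations,
    write_count_matrix,
)
from .diff_stats import pairwise_de
from .phenotypes import encode_phenotype, map_correlation, phenotype_levels, phenotype_map
from .portraits import (
    difference_portrait,
    group_mean_portrait,
    project_signature,
    read_signature,
    render_portrait,
)
from .som import SOMConfig, save_som, train_som
from .spots import (
    GeneSetCollection,
    GSZConfig,
    detect_spots,
    fisher_enrichment,
    gsz_matrix,
    read_gmt,
    upregulated_overlap,
    write_gmt,
)
from .synthetic import ModuleSpec, PhenotypeSpec, SyntheticConfig, generate_dataset

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "preprocess", "train", "portray", "diffexp",
    "spots", "gsz", "phenomap", "project",
)


class ConfigError(DataError):
    """Raised when the pipeline config is malformed."""


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    input_checksums: dict[str, str] = field(default_factory=dict)
    stages: dict[str, dict] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def record(self, stage: str, outputs: list[str], seconds: float) -> None:
        self.stages[stage] = {
            "outputs": outputs,
            "seconds": round(seconds, 3),
            "status": "completed",
        }

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(config)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ConfigError("config needs a 'simulate' or an 'inputs' block")
    return cfg


def _simulate_config(block: dict, seed: int) -> SyntheticConfig:
    modules = [ModuleSpec(**m) for m in block.get("modules", [])]
    for m in modules:
        if m.target_layers is not None:
            m.target_layers = tuple(m.target_layers)
    phen = [PhenotypeSpec(**p) for p in block.get("phenotypes", [])]
    kwargs = {
        k: v for k, v in block.items() if k not in ("modules", "phenotypes", "seed")
    }
    if "base_log_mean_range" in kwargs:
        kwargs["base_log_mean_range"] = tuple(kwargs["base_log_mean_range"])
    return SyntheticConfig(modules=modules, phenotypes=phen, seed=seed, **kwargs)


def run_pipeline(config, out_dir=None) -> RunManifest:
    """Execute all stages from a YAML config (path or mapping).

    Returns the run manifest, also written as ``manifest.json`` in the
    output directory.
    """
    cfg = _load_config(config)
    out = Path(out_dir or cfg.get("output", "somportray_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest = RunManifest(cfg, seed, _pkg_version, started=time.strftime("%FT%T"))

    def stage(name):
        t0 = time.time()
        logger.info("stage %s: starting", name)
        return t0

    try:
        # ---- simulate / ingest -------------------------------------------
        t0 = stage("simulate")
        truth = None
        if "simulate" in cfg:
            syn = _simulate_config(cfg["simulate"], seed)
            matrices, annotations, truth = generate_dataset(syn)
            outputs = []
            for name, m in matrices.items():
                p = out / f"counts_{name}.tsv"
                write_count_matrix(m, p)
                write_annotations(annotations[name], out / f"annotations_{name}.tsv")
                outputs += [str(p), str(out / f"annotations_{name}.tsv")]
            # planted modules double as gene sets and signatures downstream
            sets = {
                f"module_{m.module_id}": truth.module_genes(m.module_id)
                for m in truth.modules
            }
            write_gmt(GeneSetCollection(sets), out / "planted_modules.gmt")
            for m in truth.modules:
                sig = out / f"signature_{m.module_id}.txt"
                sig.write_text("\n".join(truth.module_genes(m.module_id)) + "\n")
                outputs.append(str(sig))
            outputs.append(str(out / "planted_modules.gmt"))
        else:
            matrices, annotations, outputs = {}, {}, []
            for entry in cfg["inputs"]["layers"]:
                name = entry["name"]
                expr, ann = Path(entry["expression"]), Path(entry["annotations"])
                for p in (expr, ann):
                    if not p.exists():
                        raise ConfigError(f"input file not found: {p}")
                    manifest.input_checksums[str(p)] = _sha256(p)
                matrices[name] = read_count_matrix(expr)
                annotations[name] = read_annotations(ann)
        manifest.record("simulate", outputs, time.time() - t0)

        # ---- preprocess ---------------------------------------------------
        t0 = stage("preprocess")
        pre = cfg.get("preprocess", {})
        layers = [
            make_layer(
                name, matrices[name], annotations[name],
                pseudocount=pre.get("pseudocount", 1.0),
                center=pre.get("center", "gene"),
            )
            for name in matrices
        ]
        ds = build_multilayer(layers)
        manifest.record("preprocess", [], time.time() - t0)

        # ---- train --------------------------------------------------------
        t0 = stage("train")
        som_block = dict(cfg.get("som", {}))
        som_block.setdefault("seed", seed)
        som_cfg = SOMConfig(**som_block)
        som = train_som(ds, som_cfg)
        som_dir = out / "som"
        save_som(som, som_dir)
        manifest.record("train", [str(som_dir)], time.time() - t0)

        # ---- portray ------------------------------------------------------
        t0 = stage("portray")
        outputs = []
        group_portraits = {}
        for lay in ds.layers:
            present = [g for g in GROUPS if lay.group_indices(g).size > 0]
            for g in present:
                port = group_mean_portrait(som, lay, g)
                group_portraits[(lay.layer_name, g)] = port
                p = out / f"portrait_{lay.layer_name}_{g}.png"
                render_portrait(port, p)
                outputs.append(str(p))
            for a, b in combinations(present, 2):
                diff = difference_portrait(
                    group_portraits[(lay.layer_name, a)],
                    group_portraits[(lay.layer_name, b)],
                )
                p = out / f"difference_{lay.layer_name}_{a}_vs_{b}.png"
                render_portrait(diff, p)
                outputs.append(str(p))
        manifest.record("portray", outputs, time.time() - t0)

        # ---- diffexp ------------------------------------------------------
        t0 = stage("diffexp")
        de_block = cfg.get("diffexp", {})
        outputs, summaries = [], {}
        for lay in ds.layers:
            present = [g for g in GROUPS if lay.group_indices(g).size >= 2]
            pairs = de_block.get("pairs") or list(combinations(present, 2))
            for a, b in pairs:
                res = pairwise_de(lay, a, b)
                tag = f"{lay.layer_name}_{a}_vs_{b}"
                p = out / f"diffexp_{tag}.tsv"
                res.table.to_csv(p, sep="\t", index=False, float_format="%.12g")
                outputs.append(str(p))
                summaries[tag] = {
                    "counts_at": {str(k): v for k, v in res.counts_at.items()},
                    "stars": res.stars,
                }
        (out / "diffexp_summary.json").write_text(json.dumps(summaries, indent=2))
        manifest.record("diffexp", outputs, time.time() - t0)

        # ---- spots --------------------------------------------------------
        t0 = stage("spots")
        spot_block = cfg.get("spots", {})
        quantile = spot_block.get("quantile", 0.98)
        min_cells = spot_block.get("min_cells", 3)
        all_spots = {}
        rows = []
        for (lname, g), port in group_portraits.items():
            spots = detect_spots(port, som, quantile=quantile, min_cells=min_cells)
            all_spots[(lname, g)] = spots
            for i, s in enumerate(spots):
                rows.append({
                    "layer": lname, "group": g, "spot": i,
                    "n_cells": s.n_cells, "n_genes": len(s.member_genes),
                    "peak_value": s.peak_value,
                    "cells": ";".join(f"{r},{c}" for r, c in sorted(s.cells)),
                })
        pd.DataFrame(rows).to_csv(out / "spots.tsv", sep="\t", index=False)
        manifest.record("spots", [str(out / "spots.tsv")], time.time() - t0)

        # ---- gsz ----------------------------------------------------------
        t0 = stage("gsz")
        gsz_block = cfg.get("gsz", {})
        gmt_path = gsz_block.get("gene_sets", out / "planted_modules.gmt")
        collection = read_gmt(gmt_path)
        gcfg = GSZConfig(lambda_stabilizer=gsz_block.get("lambda_stabilizer", 0.1))
        gsz = gsz_matrix(ds, som, collection, cfg=gcfg)
        gsz.matrix.to_csv(out / "gsz.tsv", sep="\t", float_format="%.12g")
        counts, _ = upregulated_overlap(
            gsz.matrix, z_cutoff=gsz_block.get("z_cutoff", 2.0)
        )
        counts.to_json(out / "overlap.json", indent=2)
        # Fisher enrichment of every detected spot against the collection
        fisher_rows = []
        universe = set(som.gene_ids)
        for (lname, g), spots in all_spots.items():
            for i, s in enumerate(spots):
                for set_name, genes in collection.sets.items():
                    members = set(genes) & universe
                    if not members:
                        continue
                    odds, pval = fisher_enrichment(
                        s.member_genes, members, len(universe)
                    )
                    fisher_rows.append({
                        "layer": lname, "group": g, "spot": i,
                        "gene_set": set_name, "odds_ratio": odds, "p": pval,
                    })
        pd.DataFrame(fisher_rows).to_csv(
            out / "fisher.tsv", sep="\t", index=False, float_format="%.6g"
        )
        manifest.record(
            "gsz",
            [str(out / "gsz.tsv"), str(out / "overlap.json"), str(out / "fisher.tsv")],
            time.time() - t0,
        )

        # ---- phenomap -----------------------------------------------------
        t0 = stage("phenomap")
        phen_block = cfg.get("phenomap", {})
        outputs, corr_rows = [], []
        for lay in ds.layers:
            names = phen_block.get("phenotypes") or [
                c for c in lay.annotations.columns if c != "group"
            ]
            for name in names:
                encs = []
                try:
                    encs = [encode_phenotype(lay.annotations, name)]
                except DataError:
                    for level in phenotype_levels(lay.annotations, name):
                        encs.append(encode_phenotype(lay.annotations, name, level))
                for enc in encs:
                    pmap = phenotype_map(som, lay, enc)
                    tag = f"{lay.layer_name}_{pmap.phenotype_name.replace('=', '_')}"
                    p = out / f"phenomap_{tag}.tsv"
                    pd.DataFrame(pmap.grid).to_csv(
                        p, sep="\t", index=False, float_format="%.12g"
                    )
                    outputs.append(str(p))
                    for g in GROUPS:
                        key = (lay.layer_name, g)
                        if key in group_portraits:
                            r = map_correlation(pmap, group_portraits[key])
                            corr_rows.append({
                                "layer": lay.layer_name,
                                "phenotype": pmap.phenotype_name,
                                "group": g, "pearson_r": r,
                            })
        pd.DataFrame(corr_rows).to_csv(
            out / "phenotype_correlations.tsv", sep="\t", index=False,
            float_format="%.6g",
        )
        manifest.record("phenomap", outputs, time.time() - t0)

        # ---- project ------------------------------------------------------
        t0 = stage("project")
        proj_block = cfg.get("project", {})
        sig_paths = proj_block.get("signatures") or sorted(
            str(p) for p in out.glob("signature_*.txt")
        )
        outputs = []
        rows = []
        for sp in sig_paths:
            name = Path(sp).stem
            proj = project_signature(som, read_signature(sp), name)
            for g, r, c in proj.hits:
                rows.append({"signature": name, "gene_id": g, "row": r, "col": c})
            for g in proj.misses:
                rows.append({"signature": name, "gene_id": g, "row": -1, "col": -1})
        p = out / "projections.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        manifest.record("project", [str(p)], time.time() - t0)

    except Exception as exc:
        running = [s for s in STAGES if s not in manifest.stages]
        failed = running[0] if running else "unknown"
        raise DataError(f"stage {failed!r} failed: {exc}") from exc

    manifest.finished = time.strftime("%FT%T")
    (out / "manifest.json").write_text(manifest.to_json())
    logger.info("pipeline finished: %d stages in %s", len(manifest.stages), out)
    return manifest
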