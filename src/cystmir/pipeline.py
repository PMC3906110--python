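"""End-to-end orchestration: simulate -> process -> aggregate -> DE -> variants -> mine.

A single YAML (or dict) config drives every stage; all thresholds that shape
the analysis (variant-screen alpha = 0.1, significance rule p < 0.05 with
FDR < 0.2, 200-RPM mining floor, minimum-CPM filter) live there with their
study defaults.  All randomness flows from one root seed through named
substreams, and a run manifest records the config hash and SHA-256 checksums
of every output, so an identical config + seed reproduces identical
checksums for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import os
import time

import pandas as pd
import yaml

from cystmir import diffexpr, mining, variants
from cystmir.process import process_lane
from cystmir.profiles import aggregate, quantify_absolute, to_cpm
from cystmir.simulate import SimulationConfig, make_reference, simulate_counts, synthesize_reads

STAGE_ORDER = ["simulate", "process", "aggregate", "quantify", "de", "variants", "mine"]

_FLOAT_FMT = "%.6g"


class DependencyError(RuntimeError):
    """A stage was requested without its upstream outputs."""


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(source) -> dict:
    if isinstance(source, dict):
        return dict(source)
    with open(source) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def _require(state: dict, key: str, stage: str, needed_by: str):
    if key not in state:
        raise DependencyError(
            f"stage '{needed_by}' requires output '{key}' from stage '{stage}'"
        )
    return state[key]


def run(config, out_dir: str | None = None, stages=None) -> dict:
    """Execute the requested stages in dependency order.

    Returns the run manifest (also written to ``manifest.json``); any stage
    failure aborts with an error naming the stage, and the manifest marks
    the run incomplete.
    """
    cfg = load_config(config)
    out_dir = out_dir or cfg.get("out_dir", "cystmir_run")
    os.makedirs(out_dir, exist_ok=True)
    stages = list(stages or cfg.get("stages", STAGE_ORDER))
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    stages = [s for s in STAGE_ORDER if s in stages]

    seed = int(cfg.get("seed", 0))
    sim_params = dict(cfg.get("simulation", {}))
    sim_params["seed"] = seed
    state: dict = {}
    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "stages": {},
        "outputs": {},
        "complete": False,
    }

    def emit(name: str, path: str):
        manifest["outputs"][name] = {"path": path, "sha256": _sha256(path)}

    for stage in stages:
        t0 = time.time()
        try:
            if stage == "simulate":
                sim_cfg = SimulationConfig(**sim_params)
                ref = make_reference(sim_cfg)
                counts, samples, truth = simulate_counts(sim_cfg, ref)
                reads = synthesize_reads(sim_cfg, ref, counts, samples, out_dir)
                samples_path = os.path.join(out_dir, "samples.tsv")
                samples.to_csv(samples_path, sep="\t", float_format=_FLOAT_FMT)
                truth_path = os.path.join(out_dir, "truth_units.tsv")
                truth.to_csv(truth_path, sep="\t", float_format=_FLOAT_FMT)
                state.update(
                    sim_cfg=sim_cfg, ref=ref, true_counts=counts, samples=samples,
                    reads=reads,
                )
                for name in ("fastq", "reference", "barcodes", "calibrators", "genome"):
                    emit(name, reads.paths[name])
                emit("samples", samples_path)
                emit("truth_units", truth_path)

            elif stage == "process":
                reads = _require(state, "reads", "simulate", stage)
                ref = _require(state, "ref", "simulate", stage)
                sim_cfg = state["sim_cfg"]
                with open(reads.genome_path) as fh:
                    genome = "".join(
                        ln.strip() for ln in fh if not ln.startswith(">")
                    )
                annotated, stats = process_lane(
                    reads.fastq,
                    reads.barcode_map,
                    ref,
                    sim_cfg.adapter_sequence,
                    reads.calibrators,
                    genome,
                )
                state["annotated"] = annotated
                state["mature_counts"] = annotated.mature_counts(ref)
                tallies_path = os.path.join(out_dir, "annotation_categories.tsv")
                annotated.category_tallies().to_csv(tallies_path, sep="\t")
                var_path = os.path.join(out_dir, "variant_records.tsv")
                annotated.variant_records().to_csv(var_path, sep="\t", index=False)
                counts_path = os.path.join(out_dir, "counts_mature.tsv")
                state["mature_counts"].to_tsv(counts_path)
                emit("annotation_categories", tallies_path)
                emit("variant_records", var_path)
                emit("counts_mature", counts_path)

            elif stage == "aggregate":
                mature = _require(state, "mature_counts", "process", stage)
                ref = _require(state, "ref", "simulate", stage)
                for system, tag in (("cistron", "cistron"), ("family", "family")):
                    cm = aggregate(mature, ref, system)
                    state[f"counts_{tag}"] = cm
                    path = os.path.join(out_dir, f"counts_{tag}.tsv")
                    cm.to_tsv(path)
                    emit(f"counts_{tag}", path)
                cpm_path = os.path.join(out_dir, "cpm_cistron.tsv")
                to_cpm(state["counts_cistron"]).to_csv(
                    cpm_path, sep="\t", float_format=_FLOAT_FMT
                )
                emit("cpm_cistron", cpm_path)

            elif stage == "quantify":
                annotated = _require(state, "annotated", "process", stage)
                mature = _require(state, "mature_counts", "process", stage)
                reads = _require(state, "reads", "simulate", stage)
                sim_cfg = state["sim_cfg"]
                report = quantify_absolute(
                    mature.totals,
                    annotated.calibrator_counts().sum(axis=0),
                    reads.calibrators,
                    input_ug=sim_cfg.input_ug,
                )
                path = os.path.join(out_dir, "absolute_quantification.tsv")
                report.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
                state["quantification"] = report
                emit("absolute_quantification", path)

            elif stage == "de":
                de_cfg = dict(cfg.get("de", {}))
                system = de_cfg.pop("unit_system", "cistron")
                use_sex = de_cfg.pop("covariate_sex", False)
                key = {"cistron": "counts_cistron", "family": "counts_family",
                       "mature-merged": "mature_counts"}[system]
                counts = _require(
                    state, key, "aggregate" if system != "mature-merged" else "process",
                    stage,
                )
                samples = _require(state, "samples", "simulate", stage)
                model = diffexpr.NBGLMDifferentialExpression(**de_cfg)
                model.fit(
                    counts,
                    samples["group"],
                    sex=samples["sex"] if use_sex else None,
                )
                path = os.path.join(out_dir, f"de_{system}.tsv")
                model.to_tsv(path)
                state["de"] = model
                emit(f"de_{system}", path)

            elif stage == "variants":
                annotated = _require(state, "annotated", "process", stage)
                mature = _require(state, "mature_counts", "process", stage)
                samples = _require(state, "samples", "simulate", stage)
                var_cfg = dict(cfg.get("variants", {}))
                min_reads = var_cfg.pop("min_mirna_reads", 20)
                table = variants.call_variants(
                    annotated.variant_records(), mature.counts, min_reads
                )
                table_path = os.path.join(out_dir, "variant_frequencies.tsv")
                table.to_csv(table_path, sep="\t", float_format=_FLOAT_FMT)
                emit("variant_frequencies", table_path)
                state["variant_table"] = table
                labels = (samples["group"] == state["sim_cfg"].group_labels[1]).astype(int)
                if len(table) > 0:
                    try:
                        scorer = variants.CompositeVariantScorer(**var_cfg)
                        scorer.fit(table, labels)
                        roc_path = os.path.join(out_dir, "variant_roc.json")
                        with open(roc_path, "w") as fh:
                            json.dump(
                                {
                                    "auc": scorer.auc_,
                                    "p_value": scorer.p_value_,
                                    "n_selected": int(len(scorer.selected_)),
                                    "n_case": int(labels.sum()),
                                    "n_control": int((1 - labels).sum()),
                                },
                                fh,
                                indent=1,
                            )
                        state["variant_scorer"] = scorer
                        emit("variant_roc", roc_path)
                    except ValueError:
                        pass  # no variant passed the screen; table still written

            elif stage == "mine":
                annotated = _require(state, "annotated", "process", stage)
                mature = _require(state, "mature_counts", "process", stage)
                mine_cfg = dict(cfg.get("mining", {}))
                report = mining.mine_candidates(
                    annotated.unannotated_reads(), mature.totals, **mine_cfg
                )
                path = os.path.join(out_dir, "mining_report.tsv")
                report.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
                state["mining_report"] = report
                emit("mining_report", path)

        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_manifest(manifest, out_dir)
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        manifest["stages"][stage] = {
            "status": "complete",
            "seconds": round(time.time() - t0, 3),
        }

    manifest["complete"] = all(
        v["status"] == "complete" for v in manifest["stages"].values()
    )
    _write_manifest(manifest, out_dir)
    return manifest


def _write_manifest(manifest: dict, out_dir: str) -> None:
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
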