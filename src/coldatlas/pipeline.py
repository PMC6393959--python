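"""End-to-end pipeline: simulate -> qc -> de -> classify -> specificity -> enrich.

Driven by a flat YAML/JSON config.  All stage outputs land in one run
directory together with a manifest recording inputs, parameters, the seed
and a SHA-256 digest of every written file; rerunning the same config
reproduces byte-identical TSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import de, qc, response, specificity
from .de import Contrast, DEThresholds
from .enrichment import tf_enrichment
from .io import (CountMatrix, SampleDesign, read_annotation, read_counts,
                 read_design, read_lengths, write_annotation, write_counts,
                 write_design, write_lengths)
from .simulate import SimConfig, generate_dataset, write_truth

__all__ = ["run_pipeline", "PipelineError", "DEFAULT_CONFIG"]

log = logging.getLogger("coldatlas")

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "coldatlas_run",
    "simulate": True,
    "counts": None,        # paths, used when simulate is false
    "design": None,
    "lengths": None,
    "tf_sets": None,
    "n_genes": 2000,
    "n_replicates": 3,
    "frac_de_per_contrast": 0.1,
    "dispersion": 0.05,
    "fdr_max": 0.05,
    "min_fold_change": 2.0,
    "run_specificity": True,
}

STAGES = ("simulate", "qc", "de", "classify", "specificity", "enrich")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(config_path: str | Path) -> dict:
    path = Path(config_path)
    if not path.exists():
        raise PipelineError(f"config file not found: {path}")
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(user)
    return cfg


def run_pipeline(config_path: str | Path, outdir: str | Path | None = None) -> dict:
    """Run every stage; return the manifest (also written as manifest.json)."""
    cfg = load_config(config_path)
    out = Path(outdir or cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg, "stages": {}, "outputs": {}}
    thresholds = DEThresholds(fdr_max=cfg["fdr_max"],
                              min_fold_change=cfg["min_fold_change"])
    log.info("run directory: %s", out)
    for key, val in cfg.items():
        log.info("parameter %s = %r", key, val)

    def record(stage: str, files: list[Path]) -> None:
        manifest["stages"][stage] = "PASSED"
        for f in files:
            manifest["outputs"][f.name] = _sha256(f)

    def fail(stage: str, exc: Exception) -> None:
        manifest["stages"][stage] = "FAILED"
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        _write_manifest(out, manifest)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- simulate / load ---------------------------------------------------
    try:
        if cfg["simulate"]:
            sim = SimConfig(
                n_genes=int(cfg["n_genes"]),
                n_replicates=int(cfg["n_replicates"]),
                frac_de_per_contrast=float(cfg["frac_de_per_contrast"]),
                dispersion=float(cfg["dispersion"]),
                seed=int(cfg["seed"]),
            )
            counts, design, lengths, annotations, truth = generate_dataset(sim)
            tf_sets = annotations["tf_target"]
            write_counts(counts, out / "counts.tsv")
            write_design(design, out / "design.tsv")
            write_lengths(lengths, out / "lengths.tsv")
            write_annotation(tf_sets, out / "tf_targets.tsv")
            write_truth(truth, out / "truth.tsv")
            files = [out / n for n in ("counts.tsv", "design.tsv",
                                       "lengths.tsv", "tf_targets.tsv",
                                       "truth.tsv")]
        else:
            for key in ("counts", "design", "lengths"):
                if not cfg[key] or not Path(cfg[key]).exists():
                    raise FileNotFoundError(f"input {key!r}: {cfg[key]}")
            counts = read_counts(cfg["counts"])
            design = read_design(cfg["design"])
            lengths = read_lengths(cfg["lengths"])
            design.validate_against(counts)
            tf_sets = (read_annotation(cfg["tf_sets"])
                       if cfg.get("tf_sets") else None)
            files = []
        record("simulate", files)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail("simulate", exc)

    # --- qc ----------------------------------------------------------------
    try:
        expr = qc.log_expression(counts, lengths)
        report = qc.replicate_correlation(expr, design)
        report.r2_matrix.to_csv(out / "qc_r2.tsv", sep="\t",
                                index_label="sample_id")
        _, newick = qc.cluster_samples(expr)
        (out / "samples.nwk").write_text(newick + "\n")
        (out / "qc_summary.json").write_text(json.dumps(
            {"mean_replicate_r2": report.mean_replicate_r2}, indent=2) + "\n")
        record("qc", [out / "qc_r2.tsv", out / "samples.nwk",
                      out / "qc_summary.json"])
    except Exception as exc:  # noqa: BLE001
        fail("qc", exc)

    # --- de ------------------------------------------------------------------
    try:
        results: dict[str, pd.DataFrame] = {}
        summaries = {}
        durations = sorted(
            design.table.loc[design.table["treatment"] == "cold",
                             "duration_h"].unique())
        de_files = []
        for organ in design.organs:
            for t in durations:
                contrast = Contrast(organ, int(t))
                res = de.test_contrast(counts, design, contrast, thresholds)
                results[contrast.name] = res
                summaries[contrast.name] = response.summarize_contrast(res)
                f = out / f"de_{contrast.name}.tsv"
                de.write_de_result(res, f)
                de_files.append(f)
        (out / "de_summary.json").write_text(
            json.dumps(summaries, indent=2) + "\n")
        record("de", de_files + [out / "de_summary.json"])
    except Exception as exc:  # noqa: BLE001
        fail("de", exc)

    # --- classify ------------------------------------------------------------
    try:
        classification = response.classify(results)
        classification.to_csv(out / "classification.tsv", sep="\t",
                              index_label="gene_id")
        tables = {}
        for direction in ("down", "up", "mixed"):
            tables[direction] = response.commonality(
                classification, direction).to_dict()
        (out / "commonality.json").write_text(json.dumps(tables, indent=2) + "\n")
        record("classify", [out / "classification.tsv",
                            out / "commonality.json"])
    except Exception as exc:  # noqa: BLE001
        fail("classify", exc)

    # --- specificity -----------------------------------------------------------
    try:
        if cfg["run_specificity"]:
            table = specificity.specificity_table(counts, design, lengths,
                                                  thresholds)
            table.to_csv(out / "specificity.tsv", sep="\t",
                         index_label="gene_id")
            record("specificity", [out / "specificity.tsv"])
        else:
            manifest["stages"]["specificity"] = "SKIPPED"
    except Exception as exc:  # noqa: BLE001
        fail("specificity", exc)

    # --- enrich -----------------------------------------------------------------
    try:
        if tf_sets is not None:
            de_union = set()
            universe = set()
            for res in results.values():
                universe |= set(res.index[res["tested"]])
                de_union |= set(res.index[res["status"] != "ns"])
            enr = tf_enrichment(de_union, universe, tf_sets,
                                fdr_max=thresholds.fdr_max)
            enr.to_csv(out / "tf_enrichment.tsv", sep="\t")
            record("enrich", [out / "tf_enrichment.tsv"])
        else:
            manifest["stages"]["enrich"] = "SKIPPED"
    except Exception as exc:  # noqa: BLE001
        fail("enrich", exc)

    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
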