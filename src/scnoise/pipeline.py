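"""End-to-end orchestration: QC -> noise -> classification -> DE -> overlap
-> PCA -> peak proximity, with a machine-readable JSON report.

Every stage parameter defaults to the study's published setting where one
exists (3000 detected genes per cell; prevalence log2(TPM+1) > 1 in >= 2
cells; low-expression cutoff 1.0; 20 kb TSS window).  Inputs can be files or
the built-in synthetic generator; the report records the configuration, the
dimensions surviving each filter, all test results and the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import matrix_io_qc as mio
from . import noise_variation as nv
from . import differential_expression as de
from . import enrichment_stats as es
from . import pca_structure as pca_mod
from . import peak_proximity as pp
from .synthetic_data import (SyntheticConfig, simulate_counts,
                             simulate_annotation, write_fixtures)

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    # inputs: either file paths or a synthetic configuration
    counts_path: str | None = None
    counts_format: str = "tsv"
    metadata_path: str | None = None
    lengths_path: str | None = None
    de_path: str | None = None          # external DE table; None = built-in test
    peaks_path: str | None = None
    tss_path: str | None = None
    synthetic: SyntheticConfig | None = None
    # stage parameters (study defaults)
    min_genes_per_cell: int = 3000
    prevalence_level: float = 1.0
    prevalence_min_cells: int = 2
    low_expression_cutoff: float = 1.0
    cv_on_log: bool = False
    de_alpha: float = 0.05
    tss_window: int = 20000
    overlap_rule: str = "any_overlap"
    n_pcs: int = 10
    pca_scale: bool = False
    wt_label: str = "WT"
    kd_label: str = "KD"
    outdir: str = "scnoise_out"
    seed: int = 0
    write_outputs: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            syn = dataclasses.asdict(self.synthetic)
            if syn.get("group_sizes"):
                syn["group_sizes"] = {f"{c}|{b}": v
                                      for (c, b), v in syn["group_sizes"].items()}
            d["synthetic"] = syn
        return d


@dataclass
class PipelineReport:
    config: dict
    stages: dict = field(default_factory=dict)

    def check_consistency(self) -> None:
        noise = self.stages.get("noise", {})
        counts = noise.get("variation_counts")
        if counts is not None:
            total = sum(counts.values())
            if total != noise["n_classified"]:
                raise AssertionError(
                    f"variation labels ({total}) do not partition the "
                    f"classified gene set ({noise['n_classified']})"
                )
        qc = self.stages.get("qc", {})
        if qc and noise.get("n_low_expression_retained") is not None:
            if noise["n_low_expression_retained"] > qc["genes_after_prevalence"]:
                raise AssertionError("low-expression filter retained more genes "
                                     "than survived the prevalence filter")

    def to_json(self, path=None) -> str:
        text = json.dumps({"config": self.config, "stages": self.stages},
                          indent=2, default=_jsonify)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray, pd.Index)):
        return list(obj)
    return str(obj)


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """Execute all stages; any stage error aborts with the stage name after
    persisting the partial report."""
    report = PipelineReport(config=cfg.to_dict())
    outdir = Path(cfg.outdir)
    if cfg.write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)

    def fail(stage, exc):
        if cfg.write_outputs:
            report.to_json(outdir / "report.json")
        raise StageError(stage, exc) from exc

    # ----- input -----------------------------------------------------------
    stage = "input"
    try:
        lengths = None
        peaks = tss = truth = None
        if cfg.synthetic is not None:
            syn = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
            cm, truth = simulate_counts(syn)
            lengths = truth.table["length"]
            peaks, tss = simulate_annotation(truth, window=cfg.tss_window,
                                             seed=cfg.seed)
            if cfg.write_outputs:
                write_fixtures(cm, truth, peaks, tss, outdir / "synthetic")
        else:
            if cfg.counts_path is None or cfg.metadata_path is None:
                raise ValueError("counts_path and metadata_path are required "
                                 "unless synthetic input is configured")
            cm = mio.read_count_matrix(cfg.counts_path, format=cfg.counts_format,
                                       metadata_path=cfg.metadata_path)
            if cfg.lengths_path:
                lengths = mio.read_gene_lengths(cfg.lengths_path)
            if cfg.peaks_path:
                peaks = pp.read_bed(cfg.peaks_path)
            if cfg.tss_path:
                tss = pp.read_tss_table(cfg.tss_path)
        report.stages["input"] = {
            "genes": cm.n_genes, "cells": cm.n_cells,
            "conditions": dict(cm.obs["condition"].value_counts()),
            "batches": dict(cm.obs["batch"].value_counts()),
            "synthetic": cfg.synthetic is not None,
        }
    except StageError:
        raise
    except Exception as exc:
        fail(stage, exc)

    # ----- qc / normalisation ----------------------------------------------
    stage = "qc"
    try:
        cm_f = mio.filter_cells_by_detected_genes(cm, cfg.min_genes_per_cell)
        em = mio.tpm_normalize(cm_f, lengths)
        em = mio.filter_genes_by_prevalence(em, cfg.prevalence_level,
                                            cfg.prevalence_min_cells)
        report.stages["qc"] = {
            "cells_before": cm.n_cells, "cells_after": cm_f.n_cells,
            "genes_before": cm.n_genes,
            "genes_after_prevalence": int(em.tpm.shape[0]),
        }
        if cfg.write_outputs:
            em.write_filter_log(outdir / "filter_log.json")
    except Exception as exc:
        fail(stage, exc)

    # ----- noise & variability calls ---------------------------------------
    stage = "noise"
    try:
        gnt = nv.gene_noise_stats(em, on_log=cfg.cv_on_log)
        profile = nv.noise_vs_expression_profile(
            gnt, cutoff=cfg.low_expression_cutoff)
        retained = nv.low_expression_filter(gnt, cfg.low_expression_cutoff)
        vcs = nv.classify_variation_change(gnt, retained,
                                           wt=cfg.wt_label, kd=cfg.kd_label)
        norm = nv.normality_check(vcs) if len(vcs.table) >= 20 else None
        report.stages["noise"] = {
            "n_low_expression_retained": int(len(retained)),
            "n_classified": int(len(vcs.table)),
            "n_dropped_undefined_cv": vcs.n_dropped_undefined,
            "variation_counts": vcs.counts,
            "mean_delta_cv": vcs.mean_delta,
            "sd_delta_cv": vcs.sd_delta,
            "spearman_noise_expression_low": profile.spearman_low,
            "spearman_noise_expression_high": profile.spearman_high,
            "delta_cv_normality": norm,
        }
        if cfg.write_outputs:
            gnt.to_tsv(outdir / "gene_noise.tsv")
            vcs.to_tsv(outdir / "variation_calls.tsv")
    except Exception as exc:
        fail(stage, exc)

    # ----- differential expression -----------------------------------------
    stage = "differential_expression"
    try:
        if cfg.de_path:
            der = de.import_de_results(cfg.de_path, alpha=cfg.de_alpha)
        else:
            der = de.simple_de_test(em, wt=cfg.wt_label, kd=cfg.kd_label,
                                    alpha=cfg.de_alpha)
        report.stages["differential_expression"] = {
            "method": der.method, "alpha": der.alpha, "counts": der.counts,
        }
        if cfg.write_outputs:
            der.to_tsv(outdir / "de_results.tsv")
    except Exception as exc:
        fail(stage, exc)

    # ----- overlap enrichment ----------------------------------------------
    stage = "overlap"
    try:
        universe = vcs.table.index
        overlaps = {}
        for de_lab, var_lab in (("down", "increased"), ("up", "decreased")):
            table = es.build_overlap_table(
                der.genes_with_label(de_lab), vcs.genes_with_label(var_lab),
                universe)
            entry = {"table": {"a": table.a, "b": table.b,
                               "c": table.c, "d": table.d}}
            try:
                chi2, p, fold = es.chi2_test(table)
                entry.update({"chi2": chi2, "chi2_p": p, "fold_enrichment": fold})
            except ValueError as zero_margin:
                entry["chi2_error"] = str(zero_margin)
            odds, fp = es.fisher_exact(table)
            entry.update({"fisher_odds_ratio": odds, "fisher_p": fp})
            overlaps[f"{de_lab}_vs_{var_lab}"] = entry
        report.stages["overlap"] = overlaps
    except Exception as exc:
        fail(stage, exc)

    # ----- PCA --------------------------------------------------------------
    stage = "pca"
    try:
        n_pcs = min(cfg.n_pcs, em.tpm.shape[1] - 1)
        pca = pca_mod.pca_embed(em, n_pcs=n_pcs, scale=cfg.pca_scale)
        t_cond, p_cond = pca_mod.separation_test(pca, em.obs["condition"], pc=1)
        batch_result = None
        if em.obs["batch"].nunique() == 2:
            t_b, p_b = pca_mod.separation_test(pca, em.obs["batch"], pc=1)
            batch_result = {"t": t_b, "p": p_b}
        report.stages["pca"] = {
            "n_pcs": n_pcs,
            "explained_variance_ratio": pca.explained_variance_ratio.tolist(),
            "condition_separation_pc1": {"t": t_cond, "p": p_cond},
            "batch_separation_pc1": batch_result,
        }
        if cfg.write_outputs:
            pca.scores.to_csv(outdir / "pca_scores.tsv", sep="\t",
                              index_label="cell_id")
            pca_mod.plot_embedding(pca, em.obs, "condition",
                                   outdir / "pca_condition.svg")
    except Exception as exc:
        fail(stage, exc)

    # ----- peak proximity ----------------------------------------------------
    stage = "peak_proximity"
    try:
        if peaks is None or tss is None:
            report.stages["peak_proximity"] = {"skipped": True}
        else:
            counts = pp.count_peaks_near_tss(peaks, tss, window=cfg.tss_window,
                                             rule=cfg.overlap_rule)
            comp = pp.compare_class_counts(counts, vcs)
            report.stages["peak_proximity"] = {
                "skipped": False,
                "window": cfg.tss_window,
                "class_summary": comp["summary"].to_dict(orient="index"),
                "tests": {f"{a}_vs_{b}": {"statistic": s, "p": p}
                          for (a, b), (s, p) in comp["tests"].items()},
            }
            if cfg.write_outputs:
                counts.rename("peak_count").to_csv(
                    outdir / "peak_counts.tsv", sep="\t", index_label="gene_id")
    except Exception as exc:
        fail(stage, exc)

    report.stages["seed"] = cfg.seed
    report.check_consistency()
    if cfg.write_outputs:
        report.to_json(outdir / "report.json")
    return report
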