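"""Two-condition single-cell count simulator with known ground truth.

Counts follow a negative binomial per gene and condition with variance
mu + phi * mu^2, so the expected expression noise is CV^2 = 1/mu + phi:
the sampling-noise term dominates at low expression and the curve flattens
at the biological dispersion phi for highly expressed genes.  The default
configuration emulates a Fluidigm C1 full-length design: two conditions
(WT, KD) captured on two chips (IFC1, IFC2) with 24 cells per condition per
chip, ~10,000 expressed genes, log-normal baseline means in expected counts,
and a configurable fraction of genes whose mean drops while their dispersion
rises in KD — the coupling between down-regulation and variability increase.

Matching synthetic annotation (a BED peak set and a TSS table on one
synthetic chromosome) lets the peak-proximity stage be tested end to end:
variability-increased genes receive more peaks near their TSS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix_io_qc import CountMatrix, write_count_matrix
from .peak_proximity import PeakSet, TSSTable

log = logging.getLogger(__name__)

DE_TRUTH = ("de_up", "de_down", "none")
VAR_TRUTH = ("var_up", "var_down", "none")


@dataclass
class SyntheticConfig:
    """Generative parameters; the defaults emulate the study design.

    Baseline per-gene means are log-normal in expected counts; ``fraction_de``
    genes change mean by ``mean_fold`` (half up, half down in KD) and
    ``fraction_disp`` genes change dispersion by ``disp_fold`` (half up, half
    down).  ``coupling`` is the share of dispersion-increased genes drawn from
    the mean-decreased set.  Dropout (logistic in log mean) and a per-batch
    scale factor are available but off by default, since full-length C1 data
    is far less zero-inflated than droplet data and the study found no batch
    effect.
    """

    n_genes: int = 10000
    cells_per_group: int = 24         # per condition per batch
    n_batches: int = 2
    conditions: tuple = ("WT", "KD")
    seed: int = 0
    mean_logmu: float = 2.5           # log-normal location of expected counts
    mean_logsigma: float = 1.3
    dispersion: float = 0.5           # baseline NB phi
    fraction_de: float = 0.03
    mean_fold: float = 2.0
    fraction_disp: float = 0.03
    disp_fold: float = 4.0
    coupling: float = 0.8
    dropout_midpoint: float | None = None  # logistic dropout in log(mu+1); None = off
    dropout_slope: float = 1.0
    batch_scale: float = 1.0          # multiplier applied to the second batch
    length_logmu: float = 7.5         # log-normal gene length (bases)
    length_logsigma: float = 0.7
    group_sizes: dict | None = None   # optional {(condition, batch): n} override

    def validate(self) -> None:
        problems = []
        if self.n_genes < 1:
            problems.append("n_genes must be >= 1")
        if self.cells_per_group < 2:
            problems.append("cells_per_group must be >= 2")
        for name in ("fraction_de", "fraction_disp", "coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name} must be in [0, 1], got {v}")
        for name in ("mean_fold", "disp_fold", "batch_scale"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0")
        if self.dispersion < 0:
            problems.append("dispersion must be >= 0")
        if len(self.conditions) != 2:
            problems.append("exactly two conditions are required")
        n_disp_up = round(self.n_genes * self.fraction_disp / 2)
        n_de_down = round(self.n_genes * self.fraction_de / 2)
        if round(self.coupling * n_disp_up) > n_de_down:
            problems.append(
                "coupling infeasible: coupling * n_dispersion_up exceeds the "
                "number of mean-decreased genes"
            )
        if problems:
            raise ValueError("invalid SyntheticConfig: " + "; ".join(problems))


@dataclass
class SyntheticTruth:
    """Per-gene generative parameters and true DE / variability labels."""

    table: pd.DataFrame  # index gene_id: mu_wt, mu_kd, phi_wt, phi_kd, length,
                         #                de_label, var_label
    config: SyntheticConfig = None

    def genes_with_var_label(self, label: str) -> pd.Index:
        return self.table.index[self.table["var_label"] == label]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def _nb_draw(rng, mu: np.ndarray, phi: np.ndarray, size) -> np.ndarray:
    """NB with var = mu + phi*mu^2 (Poisson where phi == 0)."""
    mu = np.broadcast_to(mu, size)
    phi = np.broadcast_to(phi, size)
    out = np.empty(size, dtype=np.int64)
    pois = phi == 0
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    if (~pois).any():
        r = 1.0 / phi[~pois]
        p = r / (r + mu[~pois])
        out[~pois] = rng.negative_binomial(r, p)
    return out


def simulate_counts(cfg: SyntheticConfig):
    """Draw a two-condition count matrix; returns (CountMatrix, SyntheticTruth)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    gene_ids = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")

    mu_wt = rng.lognormal(cfg.mean_logmu, cfg.mean_logsigma, n)
    phi_wt = np.full(n, cfg.dispersion)
    lengths = np.maximum(rng.lognormal(cfg.length_logmu, cfg.length_logsigma, n), 200.0)

    # --- truth labels -----------------------------------------------------
    de_label = np.full(n, "none", dtype=object)
    var_label = np.full(n, "none", dtype=object)
    perm = rng.permutation(n)
    n_de = round(n * cfg.fraction_de)
    n_de_up = n_de // 2
    de_up_idx = perm[:n_de_up]
    de_down_idx = perm[n_de_up:n_de]
    de_label[de_up_idx] = "de_up"
    de_label[de_down_idx] = "de_down"

    n_disp = round(n * cfg.fraction_disp)
    n_disp_up = n_disp // 2
    n_coupled = round(cfg.coupling * n_disp_up)
    if n_coupled > 0:
        coupled_idx = rng.choice(de_down_idx, size=n_coupled, replace=False)
    else:
        coupled_idx = np.array([], dtype=np.int64)
    free = perm[n_de:]  # genes with no mean change
    n_free_up = n_disp_up - n_coupled
    disp_up_idx = np.concatenate([coupled_idx, free[:n_free_up]])
    disp_down_idx = free[n_free_up:n_free_up + (n_disp - n_disp_up)]
    var_label[disp_up_idx] = "var_up"
    var_label[disp_down_idx] = "var_down"

    mu_kd = mu_wt.copy()
    mu_kd[de_up_idx] *= cfg.mean_fold
    mu_kd[de_down_idx] /= cfg.mean_fold
    phi_kd = phi_wt.copy()
    phi_kd[disp_up_idx] *= cfg.disp_fold
    phi_kd[disp_down_idx] /= cfg.disp_fold

    # --- cells ------------------------------------------------------------
    batches = [f"IFC{b + 1}" for b in range(cfg.n_batches)]
    columns, cond_labels, batch_labels = [], [], []
    blocks = []
    for cond in cfg.conditions:
        mu = mu_wt if cond == cfg.conditions[0] else mu_kd
        phi = phi_wt if cond == cfg.conditions[0] else phi_kd
        for b, batch in enumerate(batches):
            n_cells = cfg.cells_per_group
            if cfg.group_sizes is not None:
                n_cells = cfg.group_sizes.get((cond, batch), n_cells)
            scale = cfg.batch_scale if b == 1 else 1.0
            size = (n, n_cells)
            block = _nb_draw(rng, (mu * scale)[:, None], phi[:, None], size)
            if cfg.dropout_midpoint is not None:
                logmu = np.log(mu * scale + 1.0)
                p_drop = 1.0 / (1.0 + np.exp(
                    cfg.dropout_slope * (logmu - cfg.dropout_midpoint)))
                keep = rng.random(size) >= p_drop[:, None]
                block = block * keep
            blocks.append(block)
            for i in range(n_cells):
                columns.append(f"{cond}_{batch}_c{i:02d}")
                cond_labels.append(cond)
                batch_labels.append(batch)

    counts = pd.DataFrame(np.concatenate(blocks, axis=1),
                          index=gene_ids, columns=columns)
    obs = pd.DataFrame(
        {"condition": cond_labels, "batch": batch_labels},
        index=pd.Index(columns, name="cell_id"),
    )
    truth = SyntheticTruth(
        table=pd.DataFrame({
            "mu_wt": mu_wt, "mu_kd": mu_kd,
            "phi_wt": phi_wt, "phi_kd": phi_kd,
            "length": lengths,
            "de_label": de_label, "var_label": var_label,
        }, index=gene_ids),
        config=cfg,
    )
    return CountMatrix(counts=counts, obs=obs), truth


def simulate_annotation(truth: SyntheticTruth, lam_high: float = 3.0,
                        lam_low: float = 1.0, window: int = 20000,
                        peak_width: int = 200, spacing: int | None = None,
                        seed: int = 0):
    """Lay genes on a synthetic chromosome and drop peaks near their TSSs.

    Variability-increased genes receive Poisson(``lam_high``) peaks inside
    their +/- ``window`` TSS interval, all other genes Poisson(``lam_low``).
    Gene spacing is widened automatically (and logged) if the requested
    spacing would let adjacent windows overlap.
    """
    rng = np.random.default_rng(seed)
    min_spacing = 2 * window + peak_width + 1
    if spacing is None:
        spacing = min_spacing
    elif spacing < min_spacing:
        log.info("spacing %d overlaps adjacent windows; increased to %d",
                 spacing, min_spacing)
        spacing = min_spacing

    genes = truth.table.index
    tss_pos = window + np.arange(len(genes)) * spacing
    strands = np.where(np.arange(len(genes)) % 2 == 0, "+", "-")
    tss = TSSTable(
        table=pd.DataFrame(
            {"chrom": "chrS", "tss": tss_pos, "strand": strands}, index=genes
        ),
        policy="synthetic",
    )

    lam = np.where(truth.table["var_label"] == "var_up", lam_high, lam_low)
    n_peaks = rng.poisson(lam)
    rows = []
    for pos, k in zip(tss_pos, n_peaks):
        if k == 0:
            continue
        starts = rng.integers(pos - window, pos + window - peak_width + 1, size=k)
        starts = np.maximum(starts, 0)
        for s in np.sort(starts):
            rows.append({"chrom": "chrS", "start": int(s), "end": int(s + peak_width)})
    peaks = PeakSet(intervals=pd.DataFrame(rows, columns=["chrom", "start", "end"]))
    return peaks, tss


def write_fixtures(cm: CountMatrix, truth: SyntheticTruth, peaks: PeakSet,
                   tss: TSSTable, outdir, matrix_format: str = "tsv") -> dict:
    """Write matrix, metadata, truth, lengths, BED and TSS files; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = "tsv" if matrix_format == "tsv" else "mtx"
    paths = {
        "counts": outdir / f"counts.{suffix}",
        "metadata": outdir / "cell_metadata.tsv",
        "truth": outdir / "truth.tsv",
        "lengths": outdir / "gene_lengths.tsv",
        "peaks": outdir / "peaks.bed",
        "tss": outdir / "tss.tsv",
    }
    write_count_matrix(cm, paths["counts"], format=matrix_format,
                       metadata_path=paths["metadata"])
    truth.to_tsv(paths["truth"])
    truth.table["length"].round(0).astype(int).rename("length").to_csv(
        paths["lengths"], sep="\t", index_label="gene_id")
    peaks.intervals.to_csv(paths["peaks"], sep="\t", header=False, index=False)
    tss.table.to_csv(paths["tss"], sep="\t", index_label="gene_id")
    return {k: str(v) for k, v in paths.items()}
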