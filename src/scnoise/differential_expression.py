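"""Expression-changed gene calls.

Two routes are supported.  Externally produced differential-expression tables
(e.g. from an edgeR analysis of the same matrix) can be imported and labelled
at a chosen FDR.  For synthetic data and end-to-end runs without an external
table, a built-in two-group Wilcoxon rank-sum test on log2(TPM+1) is
provided; it is a deliberately simple nonparametric stand-in, not a
reimplementation of a negative-binomial GLM framework.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DE_LABELS = ("up", "down", "unchanged")


@dataclass
class DEResult:
    """Per-gene log2 fold change, p, BH-adjusted q and up/down label."""

    table: pd.DataFrame  # columns: logFC, p, q, label
    alpha: float
    method: str = "wilcoxon"

    def genes_with_label(self, label: str) -> pd.Index:
        return self.table.index[self.table["label"] == label]

    @property
    def counts(self) -> dict:
        return {lab: int((self.table["label"] == lab).sum()) for lab in DE_LABELS}

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def benjamini_hochberg(pvals) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjustment.

    q_(i) = min_{j >= i} p_(j) * m / j on the sorted p-values, clipped at 1
    and mapped back to the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def _label(logfc: np.ndarray, q: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(
        (q <= alpha) & (logfc > 0), "up",
        np.where((q <= alpha) & (logfc < 0), "down", "unchanged"),
    )


def simple_de_test(em, wt: str = "WT", kd: str = "KD",
                   condition_col: str = "condition",
                   alpha: float = 0.05) -> DEResult:
    """Per-gene two-sided Wilcoxon rank-sum test of KD vs WT.

    The test runs on log2(TPM+1) with the normal approximation (midrank ties,
    continuity correction); all-tied genes get p = 1.  logFC is
    log2((mean TPM_KD + 1) / (mean TPM_WT + 1)); q is Benjamini-Hochberg.
    """
    groups = em.obs[condition_col]
    kd_cells = (groups == kd).values
    wt_cells = (groups == wt).values
    if kd_cells.sum() < 2 or wt_cells.sum() < 2:
        raise ValueError("need >=2 cells in each condition")

    logx = em.log_expr.to_numpy(dtype=float)
    x_kd, x_wt = logx[:, kd_cells], logx[:, wt_cells]

    # genes with a single tied value across both groups carry no rank signal
    combined = np.concatenate([x_kd, x_wt], axis=1)
    tied = np.ptp(combined, axis=1) == 0

    u = np.full(len(combined), x_kd.shape[1] * x_wt.shape[1] / 2.0)
    p = np.ones(len(combined))
    if (~tied).any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.mannwhitneyu(
                x_kd[~tied], x_wt[~tied], axis=1,
                alternative="two-sided", method="asymptotic",
            )
        u[~tied] = res.statistic
        p[~tied] = res.pvalue

    tpm = em.tpm.to_numpy(dtype=float)
    logfc = np.log2(
        (tpm[:, kd_cells].mean(axis=1) + 1.0) / (tpm[:, wt_cells].mean(axis=1) + 1.0)
    )
    q = benjamini_hochberg(p)
    table = pd.DataFrame(
        {"logFC": logfc, "p": p, "q": q, "label": _label(logfc, q, alpha)},
        index=em.gene_ids,
    )
    return DEResult(table=table, alpha=alpha, method="wilcoxon")


def import_de_results(path, alpha: float = 0.05) -> DEResult:
    """Load an external DE table (gene_id, logFC, p[, q]) and label at ``alpha``.

    q is preserved verbatim when present and recomputed by Benjamini-Hochberg
    when absent.  Duplicate gene ids are an error.
    """
    tab = pd.read_csv(path, sep="\t")
    required = {"gene_id", "logFC", "p"}
    missing = required.difference(tab.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    if tab["gene_id"].duplicated().any():
        dup = tab.loc[tab["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene id in DE table: {dup!r}")
    tab = tab.set_index("gene_id")
    p = tab["p"].to_numpy(dtype=float)
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = tab["q"].to_numpy(dtype=float) if "q" in tab.columns else benjamini_hochberg(p)
    logfc = tab["logFC"].to_numpy(dtype=float)
    table = pd.DataFrame(
        {"logFC": logfc, "p": p, "q": q, "label": _label(logfc, q, alpha)},
        index=tab.index,
    )
    return DEResult(table=table, alpha=alpha, method="imported")
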