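"""Count-matrix I/O, quality-control filters and TPM normalisation.

The pipeline starts from a genes × cells matrix of read counts with a
cell-metadata table carrying a condition label (e.g. ``WT`` / ``KD``) and a
batch label (e.g. the C1 chip / IFC the cell was captured on).  Cells are
filtered by the number of detected genes, counts are normalised to
transcripts-per-million (TPM) and log2(TPM+1)-transformed, and genes are
filtered by expression prevalence.  Every filter appends a record to an
append-only ``filter_log`` so the provenance of a matrix is recoverable.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

log = logging.getLogger(__name__)

METADATA_COLUMNS = ("cell_id", "condition", "batch")

TPM_SCALE = 1e6
#: relative tolerance on per-cell TPM sums
TPM_RTOL = 1e-9


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise ValueError(f"duplicate {what} id: {dup!r}")


@dataclass
class CountMatrix:
    """Integer genes × cells count matrix with per-cell condition/batch labels.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, rows indexed by gene id, columns
        by cell id.
    obs
        Per-cell metadata indexed by cell id with ``condition`` and ``batch``
        columns; row order must match ``counts.columns``.
    filter_log
        Append-only list of dict records describing filters already applied.
    """

    counts: pd.DataFrame
    obs: pd.DataFrame
    filter_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene")
        _check_unique(self.counts.columns, "cell")
        if not self.counts.columns.equals(self.obs.index):
            extra = set(self.obs.index).symmetric_difference(self.counts.columns)
            raise ValueError(
                "cell metadata does not match matrix columns; unmatched cell "
                f"ids: {sorted(map(str, extra))[:5]}"
            )
        for col in ("condition", "batch"):
            if col not in self.obs.columns:
                raise ValueError(f"metadata missing required column {col!r}")
            if self.obs[col].isna().any():
                bad = self.obs.index[self.obs[col].isna()][0]
                raise ValueError(f"cell {bad!r} has no {col} label")
        values = self.counts.to_numpy()
        if not np.isfinite(values).all():
            g, c = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite count at gene {self.counts.index[g]!r}, "
                f"cell {self.counts.columns[c]!r}"
            )
        bad = (values < 0) | (np.mod(values, 1) != 0)
        if bad.any():
            g, c = np.argwhere(bad)[0]
            raise ValueError(
                f"count must be a non-negative integer; offending entry at "
                f"gene {self.counts.index[g]!r}, cell {self.counts.columns[c]!r} "
                f"= {values[g, c]}"
            )
        self.counts = self.counts.astype(np.int64)
        self.counts.index.name = "gene_id"
        self.counts.columns.name = None
        self.obs.index.name = "cell_id"

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def detected_genes(self) -> pd.Series:
        """Number of genes with count > 0, per cell."""
        return (self.counts > 0).sum(axis=0)


@dataclass
class ExpressionMatrix:
    """TPM-normalised expression on the same genes × cells axes.

    ``log_expr`` is always log2(TPM+1).  ``filter_log`` carries the full
    history inherited from the source :class:`CountMatrix` plus every filter
    applied at the expression level.
    """

    tpm: pd.DataFrame
    obs: pd.DataFrame
    filter_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique(self.tpm.index, "gene")
        _check_unique(self.tpm.columns, "cell")
        if not self.tpm.columns.equals(self.obs.index):
            raise ValueError("cell metadata does not match matrix columns")
        values = self.tpm.to_numpy()
        if not np.isfinite(values).all() or (values < 0).any():
            raise ValueError("TPM values must be finite and non-negative")
        sums = values.sum(axis=0)
        nonzero = sums > 0
        if self.tpm.shape[0] > 0 and not np.allclose(
            sums[nonzero], TPM_SCALE, rtol=TPM_RTOL
        ):
            # a prevalence-filtered matrix no longer sums to 1e6; allow it only
            # if the history says a gene filter ran after normalisation
            gene_filtered = any(
                rec.get("axis") == "genes" for rec in self.filter_log
            )
            if not gene_filtered:
                raise ValueError("TPM columns must each sum to 1e6")

    @property
    def log_expr(self) -> pd.DataFrame:
        """log2(TPM + 1), computed on demand."""
        return np.log2(self.tpm + 1.0)

    @property
    def gene_ids(self) -> pd.Index:
        return self.tpm.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.tpm.columns

    def write_filter_log(self, path) -> None:
        Path(path).write_text(json.dumps(self.filter_log, indent=2, default=str))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_metadata(metadata_path) -> pd.DataFrame:
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata file missing columns: {missing}")
    _check_unique(meta["cell_id"], "cell")
    return meta.set_index("cell_id")


def read_count_matrix(path, format: str = "tsv", metadata_path=None) -> CountMatrix:
    """Read a count matrix plus cell metadata.

    ``format="tsv"``: tab-separated, first column gene id, header row of cell
    ids.  ``format="mtx"``: MatrixMarket triplet file with ``<path>.rows`` and
    ``<path>.cols`` sidecars holding gene and cell ids, one per line.
    """
    path = Path(path)
    if format == "tsv":
        counts = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "mtx":
        mat = spio.mmread(path)
        genes = Path(f"{path}.rows").read_text().splitlines()
        cells = Path(f"{path}.cols").read_text().splitlines()
        counts = pd.DataFrame(
            np.asarray(sparse.coo_matrix(mat).todense()), index=genes, columns=cells
        )
    else:
        raise ValueError(f"unknown format {format!r}")

    if metadata_path is None:
        raise ValueError("metadata_path is required (condition/batch labels)")
    meta = _read_metadata(metadata_path)
    unmatched = set(meta.index).symmetric_difference(counts.columns)
    if unmatched:
        raise ValueError(
            f"metadata/matrix cell mismatch; unmatched cell ids: "
            f"{sorted(map(str, unmatched))}"
        )
    meta = meta.loc[counts.columns]
    meta.index.name = "cell_id"
    cm = CountMatrix(counts=counts, obs=meta)
    log.info(
        "read %d genes x %d cells from %s; conditions=%s batches=%s",
        cm.n_genes, cm.n_cells, path,
        dict(cm.obs["condition"].value_counts()),
        dict(cm.obs["batch"].value_counts()),
    )
    return cm


def write_count_matrix(cm: CountMatrix, path, format: str = "tsv",
                       metadata_path=None) -> None:
    """Write counts (and optionally metadata) in a round-trippable dialect."""
    path = Path(path)
    if format == "tsv":
        cm.counts.to_csv(path, sep="\t", index_label="gene_id")
    elif format == "mtx":
        spio.mmwrite(path, sparse.coo_matrix(cm.counts.to_numpy()), field="integer")
        Path(f"{path}.rows").write_text("\n".join(map(str, cm.gene_ids)) + "\n")
        Path(f"{path}.cols").write_text("\n".join(map(str, cm.cell_ids)) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    if metadata_path is not None:
        cm.obs.reset_index(names="cell_id").to_csv(metadata_path, sep="\t", index=False)


def read_gene_lengths(path) -> pd.Series:
    """Read a two-column TSV (gene_id, length) into a Series of lengths."""
    tab = pd.read_csv(path, sep="\t")
    if not {"gene_id", "length"}.issubset(tab.columns):
        raise ValueError("gene length table needs columns gene_id, length")
    _check_unique(tab["gene_id"], "gene")
    lengths = tab.set_index("gene_id")["length"].astype(float)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"non-positive length for gene {bad!r}")
    return lengths


# ---------------------------------------------------------------------------
# Normalisation and filters
# ---------------------------------------------------------------------------

def tpm_normalize(cm: CountMatrix, lengths: pd.Series | None = None) -> ExpressionMatrix:
    """Normalise counts to transcripts-per-million.

    tpm[g, c] = 1e6 * (counts[g, c] / len[g]) / sum_g'(counts[g', c] / len[g']).

    When ``lengths`` is None, all lengths are taken as 1 (counts-per-million);
    the fallback is recorded prominently in the filter log.  Per-gene
    statistics downstream (CV, noise) are unaffected because length cancels
    within a gene.
    """
    flog = list(cm.filter_log)
    if lengths is None:
        lengths = pd.Series(1.0, index=cm.gene_ids)
        flog.append({
            "step": "tpm_normalize",
            "length_fallback": "counts_per_million (all lengths = 1)",
        })
        log.warning("no gene lengths supplied; falling back to counts-per-million")
    else:
        missing = cm.gene_ids.difference(lengths.index)
        if len(missing):
            raise ValueError(
                f"gene lengths missing for {len(missing)} genes, e.g. {missing[0]!r}"
            )
        lengths = lengths.loc[cm.gene_ids].astype(float)
        if (lengths <= 0).any():
            bad = lengths.index[lengths <= 0][0]
            raise ValueError(f"zero or negative length for gene {bad!r}")
        flog.append({"step": "tpm_normalize", "length_source": "table"})

    rate = cm.counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    zero_cells = totals[totals == 0].index
    if len(zero_cells):
        warnings.warn(
            f"{len(zero_cells)} all-zero cell(s) produce all-zero TPM: "
            f"{list(map(str, zero_cells[:5]))}"
        )
    tpm = rate.div(totals.replace(0, np.nan), axis=1).fillna(0.0) * TPM_SCALE
    return ExpressionMatrix(tpm=tpm, obs=cm.obs.copy(), filter_log=flog)


def filter_cells_by_detected_genes(cm: CountMatrix, min_genes: int = 3000) -> CountMatrix:
    """Drop cells detecting fewer than ``min_genes`` genes (count > 0).

    A cell with exactly ``min_genes`` detected genes is retained (the
    threshold is a minimum, applied as >=).
    """
    detected = cm.detected_genes()
    keep = detected >= min_genes
    if not keep.any():
        raise ValueError(
            f"all {cm.n_cells} cells removed at min_genes={min_genes}; "
            "review the threshold"
        )
    removed = detected[~keep]
    flog = list(cm.filter_log)
    flog.append({
        "step": "filter_cells_by_detected_genes",
        "axis": "cells",
        "min_genes": int(min_genes),
        "before": int(cm.n_cells),
        "after": int(keep.sum()),
        "removed_detected_counts": {str(k): int(v) for k, v in removed.items()},
    })
    out = CountMatrix(
        counts=cm.counts.loc[:, keep.values],
        obs=cm.obs.loc[keep.values],
        filter_log=flog,
    )
    log.info("cell filter: %d -> %d cells (min_genes=%d)",
             cm.n_cells, out.n_cells, min_genes)
    return out


def filter_genes_by_prevalence(em: ExpressionMatrix, level: float = 1.0,
                               min_cells: int = 2) -> ExpressionMatrix:
    """Keep genes with log2(TPM+1) strictly above ``level`` in >= ``min_cells`` cells."""
    prevalent = (em.log_expr > level).sum(axis=1) >= min_cells
    if not prevalent.any():
        warnings.warn("prevalence filter removed every gene")
    flog = list(em.filter_log)
    flog.append({
        "step": "filter_genes_by_prevalence",
        "axis": "genes",
        "level": float(level),
        "min_cells": int(min_cells),
        "before": int(em.tpm.shape[0]),
        "after": int(prevalent.sum()),
    })
    return ExpressionMatrix(
        tpm=em.tpm.loc[prevalent.values],
        obs=em.obs.copy(),
        filter_log=flog,
    )


def pooled_pseudobulk(cm: CountMatrix, by: str = "condition",
                      lengths: pd.Series | None = None):
    """Sum cells within each group and correlate the pooled log profiles.

    Returns ``(profiles, r2)`` where ``profiles`` holds per-group
    log2(TPM+1) of the summed counts and ``r2`` the squared Pearson
    correlation for every group pair.
    """
    if by not in cm.obs.columns:
        raise ValueError(f"unknown grouping column {by!r}")
    groups = cm.obs[by]
    names = sorted(groups.unique())
    if len(names) < 2:
        raise ValueError(f"pooled_pseudobulk needs >=2 groups, got {len(names)}")
    if lengths is None:
        lengths = pd.Series(1.0, index=cm.gene_ids)
    else:
        lengths = lengths.loc[cm.gene_ids].astype(float)

    profiles = {}
    for name in names:
        summed = cm.counts.loc[:, (groups == name).values].sum(axis=1)
        rate = summed / lengths
        profiles[name] = np.log2(rate / rate.sum() * TPM_SCALE + 1.0)
    profiles = pd.DataFrame(profiles)

    r2 = pd.DataFrame(np.corrcoef(profiles.to_numpy(), rowvar=False) ** 2,
                      index=names, columns=names)
    return profiles, r2
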