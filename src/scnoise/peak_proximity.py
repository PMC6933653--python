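"""Regulatory-site counts near transcription start sites.

Peaks (e.g. CTCF ChIP-seq binding sites, BED intervals) are counted within a
window of each gene's TSS — by default any overlap between the peak and the
closed interval [tss - 20kb, tss + 20kb] — and the per-gene counts are
compared across differential-variability classes with Wilcoxon rank-sum
tests.  Counting uses sorted-coordinate binary search, exact and
order-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment_stats import wilcoxon_ranksum

log = logging.getLogger(__name__)

CLASS_PAIRS = (
    ("increased", "decreased"),
    ("increased", "unchanged"),
    ("decreased", "unchanged"),
)


@dataclass
class PeakSet:
    """BED intervals (0-based, half-open) with optional name/score columns."""

    intervals: pd.DataFrame  # columns: chrom, start, end [, name, score]

    def __post_init__(self):
        bad = self.intervals["start"] >= self.intervals["end"]
        if bad.any():
            row = self.intervals[bad].iloc[0]
            raise ValueError(
                f"interval start >= end: {row['chrom']}:{row['start']}-{row['end']}"
            )

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class TSSTable:
    """One strand-aware TSS per gene: columns chrom, tss (0-based), strand."""

    table: pd.DataFrame  # index gene_id
    policy: str = "unspecified"

    def __post_init__(self):
        if (self.table["tss"] < 0).any():
            bad = self.table.index[self.table["tss"] < 0][0]
            raise ValueError(f"negative TSS position for gene {bad!r}")

    def __len__(self) -> int:
        return len(self.table)


def read_bed(path) -> PeakSet:
    """Read a BED file; track/browser/comment lines are skipped."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if (not line or line.startswith("#")
                    or line.startswith("track") or line.startswith("browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            row = {"chrom": chrom, "start": start, "end": end}
            if len(fields) > 3:
                row["name"] = fields[3]
            rows.append(row)
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    if frame["name"].isna().all():
        frame = frame.drop(columns="name")
    return PeakSet(intervals=frame)


def read_tss_table(path, policy: str = "precomputed") -> TSSTable:
    """Read a TSV of gene_id, chrom, tss, strand."""
    tab = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required.difference(tab.columns)
    if missing:
        raise ValueError(f"TSS table missing columns: {sorted(missing)}")
    if tab["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in TSS table")
    return TSSTable(table=tab.set_index("gene_id"), policy=policy)


def tss_from_gtf(path, policy: str = "most_upstream") -> TSSTable:
    """Derive one TSS per gene from GTF transcript features.

    The TSS of a transcript is its 5' end in transcription direction: the
    start coordinate on + strand, the end coordinate on - strand (GTF 1-based
    inclusive coordinates are converted to 0-based positions).  With
    ``most_upstream`` the 5'-most TSS across a gene's transcripts is kept;
    with ``longest_transcript`` the TSS of the longest transcript.  Genes
    without transcript features are absent from the result.
    """
    if policy not in ("most_upstream", "longest_transcript"):
        raise ValueError(f"unknown TSS policy {policy!r}")
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    per_gene: dict = {}
    for tx in db.features_of_type("transcript"):
        gene_ids = tx.attributes.get("gene_id")
        if not gene_ids:
            log.info("transcript %s has no gene_id; skipped", tx.id)
            continue
        gene_id = gene_ids[0]
        if tx.strand == "-":
            tss = tx.end - 1  # 0-based position of the 1-based end coordinate
        else:
            tss = tx.start - 1
        length = tx.end - tx.start + 1
        per_gene.setdefault(gene_id, []).append(
            (tx.seqid, tss, tx.strand, length)
        )

    rows = {}
    for gene_id, txs in per_gene.items():
        if policy == "longest_transcript":
            chrom, tss, strand, _ = max(txs, key=lambda t: t[3])
        else:  # most_upstream: 5'-most in transcription direction
            strand = txs[0][2]
            if strand == "-":
                chrom, tss, strand, _ = max(txs, key=lambda t: t[1])
            else:
                chrom, tss, strand, _ = min(txs, key=lambda t: t[1])
        rows[gene_id] = {"chrom": chrom, "tss": int(tss), "strand": strand}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "gene_id"
    return TSSTable(table=table, policy=policy)


def _strip_chr(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


def count_peaks_near_tss(peaks: PeakSet, tss: TSSTable, window: int = 20000,
                         rule: str = "any_overlap") -> pd.Series:
    """Count peaks within ``window`` bases of each TSS.

    ``any_overlap`` (default) counts a peak when its half-open interval
    intersects the closed window [tss - window, tss + window]; a peak starting
    exactly at tss + window is counted.  ``midpoint`` counts a peak when its
    midpoint lies in the closed window.  Chromosome names are matched after
    stripping any "chr" prefix on either side (logged if applied).
    """
    if rule not in ("any_overlap", "midpoint"):
        raise ValueError(f"unknown overlap rule {rule!r}")
    iv = peaks.intervals
    peak_chroms = iv["chrom"].map(_strip_chr)
    gene_chroms = tss.table["chrom"].map(_strip_chr)
    if (peak_chroms != iv["chrom"]).any() or (gene_chroms != tss.table["chrom"]).any():
        log.info("chromosome names normalised by stripping 'chr' prefix")

    counts = pd.Series(0, index=tss.table.index, dtype=int)
    for chrom in gene_chroms.unique():
        on_chrom = iv[(peak_chroms == chrom).values]
        gene_mask = (gene_chroms == chrom).values
        positions = tss.table.loc[gene_mask, "tss"].to_numpy()
        lo = positions - window
        hi = positions + window
        if len(on_chrom) == 0:
            continue
        if rule == "midpoint":
            mids = np.sort((on_chrom["start"].to_numpy()
                            + on_chrom["end"].to_numpy()) // 2)
            n_hit = (np.searchsorted(mids, hi, side="right")
                     - np.searchsorted(mids, lo, side="left"))
        else:
            starts = np.sort(on_chrom["start"].to_numpy())
            ends = np.sort(on_chrom["end"].to_numpy())
            # overlapping peaks = all - (start beyond window) - (end at/before window)
            n_hit = (np.searchsorted(starts, hi, side="right")
                     - np.searchsorted(ends, lo, side="right"))
        counts.iloc[np.flatnonzero(gene_mask)] = n_hit
    return counts


def compare_class_counts(counts: pd.Series, vcs) -> dict:
    """Pairwise Wilcoxon comparisons of peak counts across variability classes.

    Returns ``{"summary": per-class n/mean/median frame, "tests": {(A, B):
    (statistic, p)}}``.  Genes labelled in ``vcs`` but absent from ``counts``
    get a count of 0 (logged); empty classes skip their comparisons.
    """
    labels = vcs.table["label"]
    missing = labels.index.difference(counts.index)
    if len(missing):
        log.info("%d classified genes missing peak counts; counted as 0", len(missing))
    aligned = counts.reindex(labels.index, fill_value=0)

    by_class = {lab: aligned[(labels == lab).values] for lab in labels.unique()}
    summary = pd.DataFrame({
        lab: {"n": len(v), "mean": v.mean(), "median": v.median()}
        for lab, v in by_class.items()
    }).T
    tests = {}
    for a, b in CLASS_PAIRS:
        if len(by_class.get(a, [])) == 0 or len(by_class.get(b, [])) == 0:
            log.info("class comparison %s vs %s skipped (empty class)", a, b)
            continue
        tests[(a, b)] = wilcoxon_ranksum(by_class[a], by_class[b])
    return {"summary": summary, "tests": tests}
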