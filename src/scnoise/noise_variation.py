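"""Per-gene expression noise, CV, and differential-variability calls.

Expression noise is the squared coefficient of variation, eta2 = sigma^2/mu^2,
computed per gene within each condition on linear TPM.  For count data
following a negative binomial with variance mu + phi*mu^2, the expected noise
is eta2 = 1/mu + phi: inversely proportional to expression when the mean is
small (technical/sampling regime) and flat near the biological dispersion phi
at high expression.  Genes in the low-expression regime are removed before
variability calls.

Differential variability between a knockdown (KD) and wild-type (WT)
condition is scored by dCV = CV_KD - CV_WT; genes are labelled ``increased``
when dCV > mean(dCV) + sd(dCV) and ``decreased`` when dCV < mean(dCV) -
sd(dCV), with mean and sd taken over the genes passing the low-expression
filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

STATS = ("mean", "var", "eta2", "cv")
LABELS = ("increased", "decreased", "unchanged")


@dataclass
class GeneNoiseTable:
    """Per-gene, per-condition mean, variance, noise eta2 and CV.

    ``stats`` has a (condition, statistic) MultiIndex on columns; eta2 and cv
    are missing (NaN) exactly where the condition mean is zero.
    ``mean_log_expr`` is the per-gene mean log2(TPM+1) over all retained
    cells, pooled across conditions.
    """

    stats: pd.DataFrame
    mean_log_expr: pd.Series
    on_log: bool = False

    @property
    def conditions(self) -> list:
        return list(self.stats.columns.get_level_values(0).unique())

    @property
    def gene_ids(self) -> pd.Index:
        return self.stats.index

    def condition_frame(self, condition) -> pd.DataFrame:
        return self.stats[condition]

    def to_tsv(self, path) -> None:
        flat = self.stats.copy()
        flat.columns = [f"{c}_{s}" for c, s in flat.columns]
        flat["mean_log_expr"] = self.mean_log_expr
        flat.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class VariationCallSet:
    """Differential-variability calls from the mean +/- SD rule on dCV.

    ``table`` columns: cv_wt, cv_kd, delta_cv, label.  ``mean_delta`` and
    ``sd_delta`` are the sample mean and n-1 standard deviation of delta_cv
    over exactly the classified genes.
    """

    table: pd.DataFrame
    mean_delta: float
    sd_delta: float
    wt: str
    kd: str
    n_dropped_undefined: int = 0

    def genes_with_label(self, label: str) -> pd.Index:
        return self.table.index[self.table["label"] == label]

    @property
    def counts(self) -> dict:
        return {lab: int((self.table["label"] == lab).sum()) for lab in LABELS}

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def gene_noise_stats(em, condition_col: str = "condition",
                     on_log: bool = False) -> GeneNoiseTable:
    """Compute mu, sigma^2, eta2 = sigma^2/mu^2 and CV per gene per condition.

    Statistics are taken on linear TPM by default (``on_log=True`` switches to
    log2(TPM+1), which is not the conventional CV and off by default).  The
    variance uses the n-1 denominator.  Conditions with fewer than two cells
    are an error.
    """
    conditions = sorted(em.obs[condition_col].unique())
    values = em.log_expr if on_log else em.tpm
    blocks = {}
    for cond in conditions:
        cells = (em.obs[condition_col] == cond).values
        if cells.sum() < 2:
            raise ValueError(
                f"condition {cond!r} has {int(cells.sum())} cell(s); need >=2"
            )
        x = values.loc[:, cells].to_numpy(dtype=float)
        mu = x.mean(axis=1)
        var = x.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            # cv first, eta2 as its square: keeps eta2 == cv**2 bit-exact
            cv = np.where(mu > 0, np.sqrt(var) / mu, np.nan)
        blocks[cond] = pd.DataFrame(
            {"mean": mu, "var": var, "eta2": cv**2, "cv": cv},
            index=em.gene_ids,
        )
    stats_df = pd.concat(blocks, axis=1)
    mean_log = em.log_expr.mean(axis=1)
    return GeneNoiseTable(stats=stats_df, mean_log_expr=mean_log, on_log=on_log)


@dataclass
class NoiseProfile:
    """Binned expression-vs-noise curve with split Spearman correlations."""

    bins: pd.DataFrame
    spearman_low: tuple
    spearman_high: tuple
    cutoff: float


def noise_vs_expression_profile(gnt: GeneNoiseTable, n_bins: int = 20,
                                cutoff: float = 1.0) -> NoiseProfile:
    """Equal-count bins of mean log expression vs mean noise.

    The Spearman correlation between expression and eta2 is reported
    separately for genes at or below and strictly above ``cutoff`` on pooled
    mean log2(TPM+1); noise is averaged over conditions per gene.
    """
    eta2 = pd.concat(
        [gnt.condition_frame(c)["eta2"] for c in gnt.conditions], axis=1
    ).mean(axis=1)
    ok = eta2.notna()
    expr = gnt.mean_log_expr[ok]
    eta2 = eta2[ok]
    if len(expr) < n_bins:
        raise ValueError(f"need >= {n_bins} genes with defined noise")

    order = np.argsort(expr.to_numpy(), kind="stable")
    rows = []
    for chunk in np.array_split(order, n_bins):
        rows.append({
            "mean_log_expr": float(expr.iloc[chunk].mean()),
            "mean_eta2": float(eta2.iloc[chunk].mean()),
            "n_genes": int(len(chunk)),
        })

    def _spearman(mask) -> tuple:
        if mask.sum() < 3 or expr[mask].nunique() < 2 or eta2[mask].nunique() < 2:
            return (np.nan, np.nan)
        rho, p = stats.spearmanr(expr[mask], eta2[mask])
        return (float(rho), float(p))

    low = expr <= cutoff
    return NoiseProfile(
        bins=pd.DataFrame(rows),
        spearman_low=_spearman(low),
        spearman_high=_spearman(~low),
        cutoff=cutoff,
    )


def low_expression_filter(gnt: GeneNoiseTable, cutoff: float = 1.0) -> pd.Index:
    """Genes with pooled mean log2(TPM+1) strictly above ``cutoff``.

    Genes at or below the cutoff sit in the technical-noise regime and are
    excluded from variability calls.
    """
    keep = gnt.mean_log_expr > cutoff
    if not keep.any():
        raise ValueError(f"no gene exceeds the low-expression cutoff {cutoff}")
    retained = gnt.gene_ids[keep.values]
    log.info("low-expression filter: %d of %d genes retained (cutoff=%g)",
             len(retained), len(keep), cutoff)
    return retained


def classify_variation_change(gnt: GeneNoiseTable, gene_subset,
                              wt: str = "WT", kd: str = "KD") -> VariationCallSet:
    """Label genes variation-increased/decreased by the mean +/- SD rule on dCV.

    Genes with an undefined CV in either condition (zero mean) are dropped
    before thresholding and counted in ``n_dropped_undefined``.  Both
    inequalities are strict; mean and sd of dCV use the n-1 denominator over
    the classified subset.
    """
    for cond in (wt, kd):
        if cond not in gnt.conditions:
            raise ValueError(f"condition {cond!r} not in noise table")
    cv_wt = gnt.condition_frame(wt)["cv"].loc[gene_subset]
    cv_kd = gnt.condition_frame(kd)["cv"].loc[gene_subset]
    defined = cv_wt.notna() & cv_kd.notna()
    n_dropped = int((~defined).sum())
    if n_dropped:
        log.info("dropping %d genes with undefined CV (zero mean)", n_dropped)
    cv_wt, cv_kd = cv_wt[defined], cv_kd[defined]
    if len(cv_wt) < 3:
        raise ValueError(
            f"only {len(cv_wt)} genes with defined CV; need >=3 for the sd rule"
        )

    delta = cv_kd - cv_wt
    mean_delta = float(delta.mean())
    sd_delta = float(delta.std(ddof=1))
    label = np.where(
        delta > mean_delta + sd_delta, "increased",
        np.where(delta < mean_delta - sd_delta, "decreased", "unchanged"),
    )
    table = pd.DataFrame({
        "cv_wt": cv_wt, "cv_kd": cv_kd, "delta_cv": delta, "label": label,
    })
    vcs = VariationCallSet(
        table=table, mean_delta=mean_delta, sd_delta=sd_delta,
        wt=wt, kd=kd, n_dropped_undefined=n_dropped,
    )
    log.info("variation calls: %s (mean=%.4g sd=%.4g)",
             vcs.counts, mean_delta, sd_delta)
    return vcs


def normality_check(vcs: VariationCallSet, min_genes: int = 20) -> dict:
    """Moments and omnibus normality test of the dCV distribution.

    Reports skewness, excess kurtosis and D'Agostino-Pearson K^2 with its p
    value; descriptive only, never used as a gate.  A constant dCV vector is
    degenerate and raises.
    """
    delta = vcs.table["delta_cv"].to_numpy(dtype=float)
    if len(delta) < min_genes:
        raise ValueError(f"need >= {min_genes} genes, got {len(delta)}")
    if np.ptp(delta) == 0:
        raise ValueError("dCV is constant; normality check is degenerate")
    k2, p = stats.normaltest(delta)
    return {
        "n": int(len(delta)),
        "skewness": float(stats.skew(delta)),
        "excess_kurtosis": float(stats.kurtosis(delta, fisher=True)),
        "statistic": float(k2),
        "p": float(p),
    }
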