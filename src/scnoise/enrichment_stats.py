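"""Set-overlap and enrichment statistics.

Covers the 2x2 overlap test between variation-changed and expression-changed
gene sets (Pearson chi-square, with Fisher's exact test as cross-check),
generic hypergeometric over-representation analysis with Benjamini-Hochberg
adjustment over terms, and a Wilcoxon rank-sum utility used for class
comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential_expression import benjamini_hochberg

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a (in both sets), b (A only), c (B only), d (neither)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def build_overlap_table(set_a, set_b, universe) -> ContingencyTable2x2:
    """2x2 overlap table of two gene sets within a declared universe.

    Genes outside the universe are dropped (their number is logged), then
    a = |A & B|, b = |A - B|, c = |B - A|, d = |universe| - a - b - c.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    set_a, set_b = set(set_a), set(set_b)
    dropped = len(set_a - universe) + len(set_b - universe)
    if dropped:
        log.info("build_overlap_table: dropped %d set members outside universe",
                 dropped)
    a_in, b_in = set_a & universe, set_b & universe
    a = len(a_in & b_in)
    b = len(a_in - b_in)
    c = len(b_in - a_in)
    d = len(universe) - a - b - c
    return ContingencyTable2x2(a, b, c, d)


def chi2_test(t: ContingencyTable2x2, correction: bool = False):
    """Pearson chi-square (1 df) with fold enrichment a*N/((a+b)(a+c)).

    ``correction`` applies the Yates continuity correction (off by default).
    A zero margin makes the chi-square undefined; use :func:`fisher_exact`.
    """
    arr = t.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero margin: chi-square undefined, use fisher_exact")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=correction)
    fold = t.a * t.n / ((t.a + t.b) * (t.a + t.c))
    return float(chi2), float(p), float(fold)


def fisher_exact(t: ContingencyTable2x2):
    """Two-sided Fisher exact test (sum of tables as or less probable).

    Returns the sample odds ratio (inf when b*c = 0 with a*d > 0) and the
    exact p-value.
    """
    odds, p = stats.fisher_exact(t.as_array(), alternative="two-sided")
    return float(odds), float(p)


def read_gmt(path) -> dict:
    """Parse a GMT gene-set file into {term: set of genes} (descriptions dropped)."""
    annotation = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            annotation[fields[0]] = set(g for g in fields[2:] if g)
    return annotation


def hypergeometric_ora(query_set, annotation: dict, universe,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each term in a query.

    For a term with K genes in the universe of size N and a query of size n
    overlapping k of them, p = P(X >= k) for X ~ Hypergeom(N, K, n).  Terms
    with an empty universe intersection are skipped.  Results carry BH q over
    the tested terms and are sorted by (q, p).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_set) & universe
    n = len(query)
    N = len(universe)
    rows = []
    for term, genes in annotation.items():
        term_genes = set(genes) & universe
        K = len(term_genes)
        if K == 0:
            log.info("term %r has no genes in universe; skipped", term)
            continue
        k = len(term_genes & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({
            "term": term, "overlap": k, "term_size": K,
            "expected": K * n / N, "p": min(p, 1.0),
        })
    result = pd.DataFrame(rows, columns=["term", "overlap", "term_size",
                                         "expected", "p"])
    if len(result):
        result["q"] = benjamini_hochberg(result["p"].to_numpy())
        result["significant"] = result["q"] <= alpha
        result = result.sort_values(["q", "p"], kind="stable").reset_index(drop=True)
    return result


def wilcoxon_ranksum(x, y, alternative: str = "two-sided"):
    """Wilcoxon rank-sum (Mann-Whitney U for the first sample).

    The p-value is exact (enumeration) for combined samples of at most 12
    values without ties, otherwise the normal approximation with midrank tie
    correction and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)
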