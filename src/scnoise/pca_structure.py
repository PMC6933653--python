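"""PCA of cells in log-expression space and separation/correlation tests.

Cells are embedded by PCA of log2(TPM+1) with genes centred (not unit-scaled
by default).  Condition or batch separation along a chosen component is
scored with a two-sample Student's t-test, and the association between a
single gene's expression and each component with squared Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

log = logging.getLogger(__name__)


@dataclass
class PCAResult:
    """Scores (cells x PCs), loadings (genes x PCs), explained-variance fractions."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def n_pcs(self) -> int:
        return self.scores.shape[1]


def pca_embed(em, n_pcs: int = 10, scale: bool = False) -> PCAResult:
    """PCA of cell vectors in log2(TPM+1) space.

    Genes are mean-centred; ``scale=True`` additionally divides by the gene
    standard deviation (constant genes are left unscaled).  Components carry a
    deterministic sign: the entry of largest absolute loading is positive.
    """
    x = em.log_expr.to_numpy(dtype=float).T  # cells x genes
    n_cells, n_genes = x.shape
    if n_cells < n_pcs + 1:
        raise ValueError(f"need >= {n_pcs + 1} cells for {n_pcs} PCs, got {n_cells}")
    if np.ptp(x) == 0:
        raise ValueError("constant expression matrix; PCA undefined")
    if scale:
        sd = x.std(axis=0, ddof=1)
        x = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    model = PCA(n_components=n_pcs, svd_solver="full")
    scores = model.fit_transform(x)
    components = model.components_.copy()
    for k in range(n_pcs):
        j = np.argmax(np.abs(components[k]))
        if components[k, j] < 0:
            components[k] *= -1
            scores[:, k] *= -1

    names = [f"PC{i}" for i in range(1, n_pcs + 1)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=em.cell_ids, columns=names),
        loadings=pd.DataFrame(components.T, index=em.gene_ids, columns=names),
        explained_variance_ratio=model.explained_variance_ratio_.copy(),
        params={"n_pcs": n_pcs, "scale": scale, "n_genes": n_genes,
                "centering": "gene-mean"},
    )


def separation_test(pca: PCAResult, labels, pc: int = 1, equal_var: bool = True):
    """Two-sample t-test of the two label groups on one PC coordinate.

    ``labels`` must take exactly two values over the embedded cells; groups
    are ordered by sorted label name so the sign of t is deterministic.
    ``equal_var=False`` switches to Welch's test.
    """
    labels = pd.Series(labels, index=pca.scores.index)
    names = sorted(labels.unique())
    if len(names) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(names)}: {names}")
    coord = pca.scores[f"PC{pc}"]
    g1 = coord[(labels == names[0]).values]
    g2 = coord[(labels == names[1]).values]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs >= 2 cells")
    t, p = stats.ttest_ind(g1, g2, equal_var=equal_var)
    return float(t), float(p)


def gene_pc_correlation(em, gene_id, pca: PCAResult, pcs=None) -> pd.DataFrame:
    """Squared Pearson correlation of one gene's log expression with PC scores.

    Returns a frame indexed by PC with columns r2 and p (two-sided t
    distribution p for the correlation coefficient).  A constant gene vector
    has no defined correlation and raises.
    """
    if gene_id not in em.gene_ids:
        raise KeyError(f"gene {gene_id!r} not in expression matrix")
    x = em.log_expr.loc[gene_id].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"gene {gene_id!r} is constant; correlation undefined")
    if pcs is None:
        pcs = range(1, pca.n_pcs + 1)
    rows = []
    for k in pcs:
        scores = pca.scores[f"PC{k}"].to_numpy()
        r, p = stats.pearsonr(x, scores)
        rows.append({"pc": k, "r2": float(r**2), "p": float(p)})
    return pd.DataFrame(rows).set_index("pc")


def plot_embedding(pca: PCAResult, obs: pd.DataFrame, color_by: str, path,
                   pcs=(1, 2)) -> None:
    """Scatter of two PCs coloured by a metadata column, saved to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = pca.scores[f"PC{pcs[0]}"]
    ys = pca.scores[f"PC{pcs[1]}"]
    evr = pca.explained_variance_ratio
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, group in obs.groupby(color_by):
        ax.scatter(xs.loc[group.index], ys.loc[group.index], s=18, label=str(name))
    ax.set_xlabel(f"PC{pcs[0]} ({evr[pcs[0] - 1]:.1%})")
    ax.set_ylabel(f"PC{pcs[1]} ({evr[pcs[1] - 1]:.1%})")
    ax.legend(title=color_by, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
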