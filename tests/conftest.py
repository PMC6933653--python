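import numpy as np
import pandas as pd
import pytest

from scnoise.matrix_io_qc import CountMatrix, ExpressionMatrix


def make_count_matrix(counts, conditions=None, batches=None,
                      genes=None, cells=None) -> CountMatrix:
    """Build a CountMatrix from a 2-D array with simple default labels."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    cells = cells or [f"c{i}" for i in range(n_cells)]
    if conditions is None:
        half = n_cells // 2
        conditions = ["WT"] * half + ["KD"] * (n_cells - half)
    batches = batches or ["IFC1"] * n_cells
    obs = pd.DataFrame({"condition": conditions, "batch": batches},
                       index=pd.Index(cells, name="cell_id"))
    return CountMatrix(counts=pd.DataFrame(counts, index=genes, columns=cells),
                       obs=obs)


def make_expression(values, conditions=None, batches=None,
                    genes=None, cells=None) -> ExpressionMatrix:
    """Build an ExpressionMatrix with arbitrary (already normalised) values.

    A gene-axis filter record is attached so the per-cell TPM-sum invariant
    (which only holds before gene filtering) is not enforced.
    """
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    cells = cells or [f"c{i}" for i in range(n_cells)]
    if conditions is None:
        half = n_cells // 2
        conditions = ["WT"] * half + ["KD"] * (n_cells - half)
    batches = batches or ["IFC1"] * n_cells
    obs = pd.DataFrame({"condition": conditions, "batch": batches},
                       index=pd.Index(cells, name="cell_id"))
    return ExpressionMatrix(
        tpm=pd.DataFrame(values, index=genes, columns=cells),
        obs=obs,
        filter_log=[{"step": "synthetic-test-values", "axis": "genes"}],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
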