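"""Count-matrix I/O, QC filters and TPM normalisation."""

import numpy as np
import pandas as pd
import pytest

from scnoise import matrix_io_qc as mio
from scnoise.synthetic_data import SyntheticConfig, simulate_counts

from conftest import make_count_matrix


def _write(cm, tmp_path, fmt):
    matrix = tmp_path / ("counts.tsv" if fmt == "tsv" else "counts.mtx")
    meta = tmp_path / "meta.tsv"
    mio.write_count_matrix(cm, matrix, format=fmt, metadata_path=meta)
    return matrix, meta


@pytest.mark.parametrize("fmt", ["tsv", "mtx"])
def test_roundtrip_preserves_counts_and_labels(tmp_path, fmt):
    cm = make_count_matrix([[3, 0, 5], [0, 2, 1], [7, 7, 0]],
                           conditions=["WT", "KD", "KD"],
                           batches=["IFC1", "IFC1", "IFC2"])
    matrix, meta = _write(cm, tmp_path, fmt)
    back = mio.read_count_matrix(matrix, format=fmt, metadata_path=meta)
    pd.testing.assert_frame_equal(back.counts, cm.counts)
    pd.testing.assert_frame_equal(back.obs, cm.obs)


def test_metadata_mismatch_names_unmatched_cell(tmp_path):
    cm = make_count_matrix([[1, 2], [3, 4]])
    matrix, meta = _write(cm, tmp_path, "tsv")
    extra = pd.read_csv(meta, sep="\t")
    extra = pd.concat([extra, pd.DataFrame([{"cell_id": "ghost",
                                             "condition": "WT",
                                             "batch": "IFC1"}])])
    extra.to_csv(meta, sep="\t", index=False)
    with pytest.raises(ValueError, match="ghost"):
        mio.read_count_matrix(matrix, metadata_path=meta)


@pytest.mark.parametrize("bad, message", [
    (-1, "g1.*c0|non-negative"),
    (1.5, "non-negative integer"),
])
def test_invalid_counts_name_offending_coordinate(bad, message):
    counts = pd.DataFrame([[1.0, 2.0], [float(bad), 4.0]],
                          index=["g0", "g1"], columns=["c0", "c1"])
    obs = pd.DataFrame({"condition": ["WT", "KD"], "batch": ["IFC1"] * 2},
                       index=pd.Index(["c0", "c1"], name="cell_id"))
    with pytest.raises(ValueError, match=message):
        mio.CountMatrix(counts=counts, obs=obs)


class TestTPM:
    def test_single_gene_forces_one_million(self):
        cm = make_count_matrix([[7]], conditions=["WT"])
        em = mio.tpm_normalize(cm, pd.Series({"g0": 1234.0}))
        assert em.tpm.iloc[0, 0] == pytest.approx(1e6)

    def test_hand_computed_length_normalisation(self):
        # counts {10, 20}, lengths {1000, 2000} -> equal rates -> 500000 each
        cm = make_count_matrix([[10], [20]], conditions=["WT"])
        em = mio.tpm_normalize(cm, pd.Series({"g0": 1000.0, "g1": 2000.0}))
        assert em.tpm["c0"].tolist() == pytest.approx([500000.0, 500000.0])

    def test_equal_counts_equal_lengths_symmetry(self):
        cm = make_count_matrix([[5]] * 4, conditions=["WT"])
        em = mio.tpm_normalize(cm, pd.Series(100.0, index=cm.gene_ids))
        assert np.allclose(em.tpm["c0"], 250000.0)

    def test_column_sums_are_one_million(self, rng):
        cm = make_count_matrix(rng.poisson(5, (50, 8)))
        lengths = pd.Series(rng.uniform(200, 5000, 50), index=cm.gene_ids)
        em = mio.tpm_normalize(cm, lengths)
        assert np.allclose(em.tpm.sum(axis=0), 1e6, rtol=1e-9)
        # log transform is log2(TPM+1) elementwise
        assert np.allclose(em.log_expr, np.log2(em.tpm + 1))

    def test_all_zero_cell_warns_and_stays_zero(self):
        cm = make_count_matrix([[1, 0], [2, 0]])
        with pytest.warns(UserWarning, match="all-zero"):
            em = mio.tpm_normalize(cm, pd.Series(1000.0, index=cm.gene_ids))
        assert (em.tpm["c1"] == 0).all()

    def test_missing_length_is_error(self):
        cm = make_count_matrix([[1], [2]], conditions=["WT"])
        with pytest.raises(ValueError, match="missing"):
            mio.tpm_normalize(cm, pd.Series({"g0": 1000.0}))

    def test_cpm_fallback_is_recorded(self):
        cm = make_count_matrix([[1], [3]], conditions=["WT"])
        em = mio.tpm_normalize(cm, None)
        assert any("counts_per_million" in str(rec) for rec in em.filter_log)


class TestCellFilter:
    @pytest.mark.parametrize("detected, min_genes, kept", [
        (3, 3, True),    # exactly at the minimum: retained (>=)
        (2, 3, False),   # one below: removed
    ])
    def test_threshold_is_inclusive(self, detected, min_genes, kept):
        col = [1] * detected + [0] * (4 - detected)
        cm = make_count_matrix(np.array([col, [1, 1, 1, 1]]).T,
                               conditions=["WT", "KD"])
        out = mio.filter_cells_by_detected_genes(cm, min_genes=min_genes)
        assert ("c0" in out.cell_ids) == kept

    def test_zero_threshold_is_identity(self):
        cm = make_count_matrix([[0, 1], [0, 2]])
        out = mio.filter_cells_by_detected_genes(cm, min_genes=0)
        pd.testing.assert_frame_equal(out.counts, cm.counts)

    def test_all_cells_removed_raises(self):
        cm = make_count_matrix([[1, 1], [0, 0]])
        with pytest.raises(ValueError, match="threshold"):
            mio.filter_cells_by_detected_genes(cm, min_genes=100)

    def test_removal_recorded_with_detected_counts(self):
        cm = make_count_matrix([[1, 0], [1, 0]])
        out = mio.filter_cells_by_detected_genes(cm, min_genes=1)
        rec = out.filter_log[-1]
        assert rec["removed_detected_counts"] == {"c1": 0}


class TestPrevalenceFilter:
    def _em(self, tpm_values):
        cm = make_count_matrix(np.ones((len(tpm_values), 4), dtype=int))
        em = mio.tpm_normalize(cm, None)
        em.tpm.iloc[:, :] = np.asarray(tpm_values, dtype=float)
        em.filter_log.append({"axis": "genes", "step": "test-values"})
        return em

    def test_boundary_exactly_two_cells_kept_one_removed(self):
        # log2(TPM+1) > 1 means TPM > 1
        em = self._em([[1.5, 1.5, 0.0, 0.0],   # above in exactly 2 cells -> kept
                       [1.5, 0.0, 0.0, 0.0],   # above in exactly 1 cell  -> removed
                       [0.0, 0.0, 0.0, 0.0]])  # all-zero -> removed
        out = mio.filter_genes_by_prevalence(em, level=1.0, min_cells=2)
        assert list(out.gene_ids) == ["g0"]

    def test_strictly_greater_at_level(self):
        # TPM exactly 1 gives log2(2) == 1, not > 1: never counted
        em = self._em([[1.0, 1.0, 1.0, 1.0]])
        with pytest.warns(UserWarning, match="every gene"):
            out = mio.filter_genes_by_prevalence(em, level=1.0, min_cells=2)
        assert len(out.gene_ids) == 0

    def test_idempotent(self, rng):
        cm = make_count_matrix(rng.poisson(2, (40, 6)))
        em = mio.tpm_normalize(cm, None)
        once = mio.filter_genes_by_prevalence(em)
        twice = mio.filter_genes_by_prevalence(once)
        pd.testing.assert_frame_equal(once.tpm, twice.tpm)


def test_filters_commute_with_reordering(rng):
    cm = make_count_matrix(rng.poisson(3, (30, 8)))
    gene_perm = rng.permutation(30)
    cell_perm = rng.permutation(8)
    permuted = mio.CountMatrix(
        counts=cm.counts.iloc[gene_perm, cell_perm],
        obs=cm.obs.iloc[cell_perm],
    )
    for m in (cm, permuted):
        m_f = mio.filter_cells_by_detected_genes(m, min_genes=10)
        em = mio.filter_genes_by_prevalence(mio.tpm_normalize(m_f, None))
        if m is cm:
            base = em
        else:
            perm_result = em
    pd.testing.assert_frame_equal(
        perm_result.tpm.sort_index(axis=0).sort_index(axis=1),
        base.tpm.sort_index(axis=0).sort_index(axis=1),
    )


class TestPseudobulk:
    def test_group_self_correlation_is_one(self, rng):
        cm = make_count_matrix(rng.poisson(10, (100, 6)))
        _, r2 = mio.pooled_pseudobulk(cm, by="condition")
        assert np.allclose(np.diag(r2), 1.0)

    def test_identical_generative_params_highly_correlated(self, rng):
        mu = rng.lognormal(2, 1.5, 5000)
        counts = rng.poisson(np.tile(mu[:, None], (1, 40)))
        cm = make_count_matrix(counts)
        profiles, r2 = mio.pooled_pseudobulk(cm, by="condition")
        # oracle: independent Pearson computation on the pooled profiles
        expected = np.corrcoef(profiles["WT"], profiles["KD"])[0, 1] ** 2
        assert r2.loc["WT", "KD"] == pytest.approx(expected, abs=1e-12)
        assert r2.loc["WT", "KD"] > 0.9

    def test_permuted_gene_means_decorrelate(self, rng):
        mu = rng.lognormal(2, 1.5, 5000)
        a = rng.poisson(np.tile(mu[:, None], (1, 20)))
        b = rng.poisson(np.tile(rng.permutation(mu)[:, None], (1, 20)))
        cm = make_count_matrix(np.hstack([a, b]))
        _, r2 = mio.pooled_pseudobulk(cm, by="condition")
        assert r2.loc["WT", "KD"] < 0.1

    def test_single_group_is_error(self):
        cm = make_count_matrix([[1, 2], [3, 4]], conditions=["WT", "WT"])
        with pytest.raises(ValueError, match="2 groups"):
            mio.pooled_pseudobulk(cm, by="condition")


def test_synthetic_fixtures_roundtrip_through_readers(tmp_path):
    cfg = SyntheticConfig(n_genes=50, cells_per_group=3, seed=4)
    cm, truth = simulate_counts(cfg)
    matrix, meta = _write(cm, tmp_path, "mtx")
    back = mio.read_count_matrix(matrix, format="mtx", metadata_path=meta)
    assert (back.counts.to_numpy() == cm.counts.to_numpy()).all()
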