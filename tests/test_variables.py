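import numpy as np
import pandas as pd
import pytest

from ripchip.sequences import BindingSiteMatrix
from ripchip.variables import (
    VARIABLE_NAMES,
    VariableTable,
    compute_single_variable,
    compute_variables,
    variable_correlation_matrix,
)


def make_inputs(rng, n_mirnas=4, n_genes=3):
    mirnas = [f"m{i}" for i in range(n_mirnas)]
    genes = [f"G{j}" for j in range(n_genes)]
    L1 = pd.Series(rng.integers(60, 400, n_genes).astype(float), index=genes)
    L2 = pd.Series(rng.integers(100, 800, n_genes).astype(float), index=genes)

    def bsm(lens, region):
        counts = rng.poisson(3.0, size=(n_mirnas, n_genes)).astype(float)
        bs = BindingSiteMatrix(
            values=pd.DataFrame(counts, index=pd.Index(mirnas, name="mirna_id"),
                                columns=genes),
            region=region, mode="count")
        dbs = BindingSiteMatrix(values=bs.values / lens, region=region, mode="density")
        return bs, dbs

    bs_utr, dbs_utr = bsm(L1, "utr3")
    bs_cds, dbs_cds = bsm(L2, "cds")
    e = pd.Series(rng.lognormal(0, 1, n_mirnas), index=mirnas)
    g = pd.Series(rng.lognormal(0, 1, n_genes), index=genes)
    lengths = pd.DataFrame({"L1": L1, "L2": L2})
    return e, g, bs_utr, bs_cds, dbs_utr, dbs_cds, lengths


def triple_loop_oracle(e, g, bs_utr, bs_cds, dbs_utr, dbs_cds, lengths, subset):
    """Literal per-gene, per-miRNA summation of every formula."""
    out = {}
    for gene in g.index:
        row = {}
        for names, mat in ((("F1", "F2", "F3", "F4"), bs_utr),
                           (("F1d", "F2d", "F3d", "F4d"), dbs_utr),
                           (("F5", "F6", "F7", "F8"), bs_cds),
                           (("F5d", "F6d", "F7d", "F8d"), dbs_cds)):
            s_ew = sum(e[m] * mat.values.loc[m, gene] for m in subset)
            s_uw = sum(mat.values.loc[m, gene] for m in subset)
            row[names[0]] = s_ew * g[gene]
            row[names[1]] = s_ew
            row[names[2]] = s_uw * g[gene]
            row[names[3]] = s_uw
        row["F9"] = g[gene]
        row["L1"] = lengths.loc[gene, "L1"]
        row["L2"] = lengths.loc[gene, "L2"]
        out[gene] = row
    return pd.DataFrame(out).T[list(VARIABLE_NAMES)]


class TestComputeVariables:
    def test_expression_zero_mirna_drops_out_of_f6(self):
        rng = np.random.default_rng(0)
        e, g, bs_utr, bs_cds, dbs_utr, dbs_cds, lengths = make_inputs(rng, 2, 1)
        e[:] = [10.0, 0.0]
        bs_cds.values.iloc[:, 0] = [1.0, 5.0]
        vt = compute_variables(e, g, bs_utr, bs_cds, dbs_utr, dbs_cds, lengths,
                               mirna_subset=list(e.index))
        assert vt["F6"].iloc[0] == 10.0

    def test_unit_weights_small_case(self):
        rng = np.random.default_rng(0)
        e, g, bs_utr, bs_cds, dbs_utr, dbs_cds, lengths = make_inputs(rng, 2, 1)
        e[:] = 1.0
        g[:] = 2.0
        bs_utr.values.iloc[:, 0] = [1.0, 1.0]
        vt = compute_variables(e, g, bs_utr, bs_cds, dbs_utr, dbs_cds, lengths,
                               mirna_subset=list(e.index))
        assert vt["F1"].iloc[0] == 4.0
        assert vt["F2"].iloc[0] == 2.0
        assert vt["F3"].iloc[0] == 4.0
        assert vt["F4"].iloc[0] == 2.0

    def test_zero_bs_column_zeroes_site_variables_only(self):
        rng = np.random.default_rng(1)
        e, g, bs_utr, bs_cds, dbs_utr, dbs_cds, lengths = make_inputs(rng, 3, 2)
        for m in (bs_utr, bs_cds, dbs_utr, dbs_cds):
            m.values.iloc[:, 0] = 0.0
        vt = compute_variables(e, g, bs_utr, bs_cds, dbs_utr, dbs_cds, lengths,
                               mirna_subset=list(e.index))
        gene = vt.gene_ids[0]
        site_vars = [n for n in VARIABLE_NAMES if n.startswith("F") and n != "F9"]
        assert all(vt[n][gene] == 0.0 for n in site_vars)
        assert vt["F9"][gene] == g[gene]
        assert vt["L1"][gene] == lengths.loc[gene, "L1"]

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(5)
        e, g, bs_utr, bs_cds, dbs_utr, dbs_cds, lengths = make_inputs(rng, 20, 5)
        subset = list(e.index)
        vt = compute_variables(e, g, bs_utr, bs_cds, dbs_utr, dbs_cds, lengths,
                               mirna_subset=subset)
        expected = triple_loop_oracle(e, g, bs_utr, bs_cds, dbs_utr, dbs_cds,
                                      lengths, subset)
        assert np.allclose(vt.table, expected.loc[vt.gene_ids], rtol=1e-12, atol=1e-12)

    def test_subset_restriction_limits_sums(self):
        rng = np.random.default_rng(2)
        e, g, bs_utr, bs_cds, dbs_utr, dbs_cds, lengths = make_inputs(rng, 4, 3)
        full = compute_variables(e, g, bs_utr, bs_cds, dbs_utr, dbs_cds, lengths,
                                 mirna_subset=list(e.index))
        top2 = compute_variables(e, g, bs_utr, bs_cds, dbs_utr, dbs_cds, lengths,
                                 mirna_subset=2)
        assert (top2["F4"] <= full["F4"]).all()
        assert len(top2.mirna_subset) == 2

    def test_mirna_scaling_property(self):
        rng = np.random.default_rng(3)
        e, g, bs_utr, bs_cds, dbs_utr, dbs_cds, lengths = make_inputs(rng, 5, 4)
        subset = list(e.index)
        v1 = compute_variables(e, g, bs_utr, bs_cds, dbs_utr, dbs_cds, lengths,
                               mirna_subset=subset)
        v2 = compute_variables(3.0 * e, g, bs_utr, bs_cds, dbs_utr, dbs_cds, lengths,
                               mirna_subset=subset)
        for name in ("F1", "F2", "F5", "F6", "F1d", "F2d", "F5d", "F6d"):
            assert np.allclose(v2[name], 3.0 * v1[name], rtol=1e-12)
        for name in ("F3", "F4", "F7", "F8", "F9", "L1", "L2"):
            assert np.allclose(v2[name], v1[name], rtol=1e-12)

    def test_density_times_length_identity(self):
        rng = np.random.default_rng(4)
        e, g, bs_utr, bs_cds, dbs_utr, dbs_cds, lengths = make_inputs(rng, 6, 5)
        vt = compute_variables(e, g, bs_utr, bs_cds, dbs_utr, dbs_cds, lengths,
                               mirna_subset=list(e.index))
        assert np.allclose(vt["F4d"] * vt["L1"], vt["F4"], rtol=1e-12)
        assert np.allclose(vt["F8d"] * vt["L2"], vt["F8"], rtol=1e-12)

    def test_unaligned_mirnas_rejected(self):
        rng = np.random.default_rng(6)
        e, g, bs_utr, bs_cds, dbs_utr, dbs_cds, lengths = make_inputs(rng, 3, 2)
        with pytest.raises(ValueError, match="m0"):
            compute_variables(e.drop("m0"), g, bs_utr, bs_cds, dbs_utr, dbs_cds,
                              lengths, mirna_subset=["m1"])

    def test_single_variable_agrees_with_table(self):
        rng = np.random.default_rng(7)
        e, g, bs_utr, bs_cds, dbs_utr, dbs_cds, lengths = make_inputs(rng, 5, 4)
        vt = compute_variables(e, g, bs_utr, bs_cds, dbs_utr, dbs_cds, lengths,
                               mirna_subset=3)
        for name in ("F6", "F4d", "L2"):
            single = compute_single_variable(name, e, g, bs_utr, bs_cds, dbs_utr,
                                             dbs_cds, lengths, mirna_subset=3)
            assert np.allclose(single, vt[name], rtol=1e-12)


class TestCorrelationMatrix:
    def _table(self, rng, n=40):
        frame = pd.DataFrame(
            rng.lognormal(0, 1, size=(n, len(VARIABLE_NAMES))),
            columns=list(VARIABLE_NAMES),
            index=[f"G{i}" for i in range(n)],
        )
        return VariableTable(table=frame, mirna_subset=[])

    def test_unit_diagonal_and_symmetry(self, rng):
        corr = variable_correlation_matrix(self._table(rng))
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)
        assert (corr.to_numpy() <= 1.0 + 1e-12).all()

    def test_scaled_duplicate_column_correlates_perfectly(self, rng):
        vt = self._table(rng)
        vt.table["F1"] = 2.0 * vt.table["F4"]
        corr = variable_correlation_matrix(vt)
        assert corr.loc["F1", "F4"] == pytest.approx(1.0)

    def test_hand_computed_three_gene_pearson(self):
        frame = pd.DataFrame(
            {name: [1.0, 2.0, 4.0] for name in VARIABLE_NAMES},
            index=["G0", "G1", "G2"],
        )
        frame["F4"] = [1.0, 2.0, 3.0]
        # Pearson of (1,2,4) vs (1,2,3) by hand: cov=1.5/..., r = 0.98198...
        x = np.array([1.0, 2.0, 4.0])
        y = np.array([1.0, 2.0, 3.0])
        r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        corr = variable_correlation_matrix(VariableTable(table=frame, mirna_subset=[]))
        assert corr.loc["F1", "F4"] == pytest.approx(r, rel=1e-12)

    def test_zero_variance_column_is_undefined_not_zero(self, rng):
        vt = self._table(rng)
        vt.table["L1"] = 7.0
        corr = variable_correlation_matrix(vt)
        assert corr.loc["L1"].isna().all()

    def test_site_count_tracks_region_length(self, gw182_dataset):
        ds = gw182_dataset
        vt = compute_variables(ds.mirna_profile, ds.mrna_profile, ds.bs_utr,
                               ds.bs_cds, ds.dbs_utr, ds.dbs_cds, ds.lengths)
        # Poisson site counts with rate ~ length: more coding sequence,
        # more predicted sites
        assert vt.table["F8"].corr(vt.table["L2"]) > 0.5

    def test_tsv_round_trip(self, tmp_path, rng):
        vt = self._table(rng, n=10)
        vt.mirna_subset = ["m1", "m2"]
        vt.to_tsv(tmp_path / "v.tsv")
        back = VariableTable.read_tsv(tmp_path / "v.tsv")
        assert np.allclose(back.table, vt.table)
        assert back.mirna_subset == ["m1", "m2"]
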