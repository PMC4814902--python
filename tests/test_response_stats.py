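import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import drugprior as dp
from conftest import make_binary_matrix


class TestClassifyCells:
    def test_threshold_boundary_counts_as_sensitive(self):
        ic50 = pd.DataFrame({"A": [0.5, 0.5, 0.5]}, index=["c1", "c2", "c3"])
        labels = dp.classify_cells(dp.DrugResponseTable(ic50=ic50), "A")
        assert labels.sensitive == ["c1", "c2", "c3"] and not labels.resistant

    def test_partition_matches_reference_resistant_majority(self):
        # 448 assayed lines, 446 above 0.5 μM: the most resistant-skewed
        # partition in the reference panel (an MDM2 inhibitor)
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.uniform(0.51, 8.0, 446), [0.1, 0.4]])
        ic50 = pd.DataFrame({"D": vals},
                            index=[f"c{i}" for i in range(448)])
        labels = dp.classify_cells(dp.DrugResponseTable(ic50=ic50), "D")
        assert (len(labels.resistant), len(labels.sensitive)) == (446, 2)

    def test_missing_ic50_excluded_and_absent_drug_errors(self, tiny_response):
        labels = dp.classify_cells(tiny_response, "B")
        assert "c2" not in labels.resistant + labels.sensitive
        with pytest.raises(KeyError):
            dp.classify_cells(tiny_response, "nope")

    @given(st.integers(0, 2**31 - 1))
    def test_counts_match_brute_force_tally(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        vals = rng.lognormal(-0.7, 1.2, n)
        ic50 = pd.DataFrame({"A": vals}, index=[f"c{i}" for i in range(n)])
        labels = dp.classify_cells(dp.DrugResponseTable(ic50=ic50), "A")
        assert len(labels.sensitive) == int((vals <= 0.5).sum())
        assert len(labels.resistant) == int((vals > 0.5).sum())
        assert labels.n_assayed == n


class TestBinaryBias:
    def test_reference_fraction_quadruples(self):
        # worked examples from the bundled 24-drug reference table
        r = dp.BiasResult("17AAG", "SPEN", 21, 97, 38, 350)
        assert r.rounded() == (0.216, 0.109, 0.107)
        r = dp.BiasResult("PF2341066", "PDE4DIP", 241, 436, 2, 12)
        assert r.rounded() == (0.553, 0.167, 0.386)

    def test_zero_mutants_give_zero_bias(self, tiny_response):
        labels = dp.classify_cells(tiny_response, "A")
        mat = make_binary_matrix(0.0, tiny_response.cell_lines, ["G1"])
        r = dp.binary_bias(labels, mat, "G1")
        assert (r.f_res, r.f_sen, r.diff) == (0.0, 0.0, 0.0)

    def test_empty_group_raises_with_group_name(self):
        ic50 = pd.DataFrame({"A": [1.0, 2.0]}, index=["c1", "c2"])
        labels = dp.classify_cells(dp.DrugResponseTable(ic50=ic50), "A")
        mat = make_binary_matrix(1.0, ["c1", "c2"], ["G1"])
        with pytest.raises(dp.DataError, match="sensitive"):
            dp.binary_bias(labels, mat, "G1")

    def test_bias_invariant_under_cell_reordering(self, small_dataset):
        drug = small_dataset.response.drugs[0]
        labels = dp.classify_cells(small_dataset.response, drug)
        mat = small_dataset.matrices["mutation"]
        gene = mat.genes[0]
        shuffled = dp.FeatureMatrix(
            "mutation", mat.values.sample(frac=1.0, random_state=1)
        )
        a = dp.binary_bias(labels, mat, gene)
        b = dp.binary_bias(labels, shuffled, gene)
        assert (a.mut_res, a.n_res, a.mut_sen, a.n_sen) == (
            b.mut_res, b.n_res, b.mut_sen, b.n_sen)

    @given(st.integers(0, 2**31 - 1))
    def test_diff_bounded_and_partition_conserved(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        cells = [f"c{i}" for i in range(n)]
        ic50 = pd.DataFrame({"A": rng.lognormal(-0.7, 1.0, n)}, index=cells)
        resp = dp.DrugResponseTable(ic50=ic50)
        labels = dp.classify_cells(resp, "A")
        assert labels.n_assayed == n
        if not labels.resistant or not labels.sensitive:
            return
        mat = make_binary_matrix(
            rng.integers(0, 2, (n, 1)).astype(float), cells, ["G1"])
        r = dp.binary_bias(labels, mat, "G1")
        assert -1.0 <= r.diff <= 1.0
        assert r.total == n


class TestBiasTable:
    def test_sorted_by_diff_descending(self, tiny_response):
        labels = dp.classify_cells(tiny_response, "A")  # sens c1,c3; res c2,c4
        mat = make_binary_matrix(
            [[0, 0], [1, 0], [0, 0], [1, 1]],
            tiny_response.cell_lines, ["B_gene", "A_gene"],
        )
        table = dp.bias_table(labels, mat)
        assert [r.gene for r in table] == ["B_gene", "A_gene"]
        assert table[0].diff == 1.0 and table[1].diff == 0.5

    def test_single_gene_call_consistent_with_table(self, small_dataset):
        drug = small_dataset.response.drugs[1]
        labels = dp.classify_cells(small_dataset.response, drug)
        mat = small_dataset.matrices["mutation"]
        table = {r.gene: r for r in dp.bias_table(labels, mat)}
        gene = mat.genes[5]
        single = dp.binary_bias(labels, mat, gene)
        assert table[gene].diff == single.diff

    def test_ordering_matches_brute_force_sort(self, small_dataset):
        drug = small_dataset.response.drugs[0]
        labels = dp.classify_cells(small_dataset.response, drug)
        mat = dp.FeatureMatrix(
            "mutation", small_dataset.matrices["mutation"].values.iloc[:, :20]
        )
        table = dp.bias_table(labels, mat)
        expected = sorted(
            ((dp.binary_bias(labels, mat, g)) for g in mat.genes),
            key=lambda r: (-r.diff, r.gene),
        )
        assert [r.gene for r in table] == [r.gene for r in expected]


class TestContinuousStats:
    def test_equal_group_means_give_zero_diff(self):
        cells = ["c1", "c2", "c3", "c4"]
        ic50 = pd.DataFrame({"A": [0.1, 0.2, 2.0, 4.0]}, index=cells)
        resp = dp.DrugResponseTable(ic50=ic50)
        labels = dp.classify_cells(resp, "A")
        mat = dp.FeatureMatrix(
            "expression",
            pd.DataFrame({"G1": [3.0, 5.0, 3.0, 5.0]}, index=cells),
        )
        r = dp.continuous_stats(labels, mat, ic50["A"], "G1")
        assert r.diff == pytest.approx(0.0)

    def test_self_correlation_is_one(self):
        cells = [f"c{i}" for i in range(10)]
        vals = np.linspace(0.1, 3.0, 10)
        ic50 = pd.DataFrame({"A": vals}, index=cells)
        resp = dp.DrugResponseTable(ic50=ic50)
        labels = dp.classify_cells(resp, "A")
        mat = dp.FeatureMatrix(
            "expression", pd.DataFrame({"G1": vals}, index=cells))
        r = dp.continuous_stats(labels, mat, ic50["A"], "G1")
        assert r.r_ic50 == pytest.approx(1.0)

    def test_zero_variance_feature_gives_nan_not_zero(self):
        cells = [f"c{i}" for i in range(6)]
        ic50 = pd.DataFrame({"A": np.linspace(0.1, 2, 6)}, index=cells)
        labels = dp.classify_cells(dp.DrugResponseTable(ic50=ic50), "A")
        mat = dp.FeatureMatrix(
            "expression", pd.DataFrame({"G1": [4.0] * 6}, index=cells))
        r = dp.continuous_stats(labels, mat, ic50["A"], "G1")
        assert np.isnan(r.r_ic50)

    def test_matches_direct_two_pass_computation(self):
        rng = np.random.default_rng(7)
        n = 30
        cells = [f"c{i}" for i in range(n)]
        feat = rng.normal(7, 2, n)
        vals = rng.lognormal(-0.7, 1.0, n)
        ic50 = pd.DataFrame({"A": vals}, index=cells)
        resp = dp.DrugResponseTable(ic50=ic50)
        labels = dp.classify_cells(resp, "A")
        mat = dp.FeatureMatrix(
            "expression", pd.DataFrame({"G1": feat}, index=cells))
        r = dp.continuous_stats(labels, mat, ic50["A"], "G1")
        res_mask = vals > 0.5
        assert r.mean_res == pytest.approx(feat[res_mask].mean())
        assert r.mean_sen == pytest.approx(feat[~res_mask].mean())
        direct = (np.sum((feat - feat.mean()) * (vals - vals.mean()))
                  / np.sqrt(np.sum((feat - feat.mean()) ** 2)
                            * np.sum((vals - vals.mean()) ** 2)))
        assert r.r_ic50 == pytest.approx(direct)


class TestMutantVsWildTest:
    def test_power_under_tenfold_shift(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(30):
            n = 40
            cells = [f"c{i}" for i in range(n)]
            gene = np.r_[np.ones(20), np.zeros(20)]
            ic50 = np.r_[10 * rng.lognormal(0, 0.5, 20),
                         rng.lognormal(0, 0.5, 20)]
            resp = dp.DrugResponseTable(
                pd.DataFrame({"D": ic50}, index=cells))
            mat = make_binary_matrix(gene.reshape(-1, 1), cells, ["G"])
            rec = dp.mutant_vs_wild_test(resp, mat, "G", "D")
            hits += rec.p_value < 0.05
        assert hits >= 27  # large majority

    def test_identical_constant_groups_undefined_p(self):
        cells = [f"c{i}" for i in range(8)]
        gene = np.r_[np.ones(4), np.zeros(4)]
        resp = dp.DrugResponseTable(
            pd.DataFrame({"D": [2.0] * 8}, index=cells))
        mat = make_binary_matrix(gene.reshape(-1, 1), cells, ["G"])
        rec = dp.mutant_vs_wild_test(resp, mat, "G", "D")
        assert rec.diff_ic50 == 0.0 and not rec.testable

    def test_small_group_flagged_untestable(self):
        cells = [f"c{i}" for i in range(5)]
        gene = np.r_[np.ones(1), np.zeros(4)]
        resp = dp.DrugResponseTable(
            pd.DataFrame({"D": [0.2, 1, 2, 3, 4]}, index=cells))
        mat = make_binary_matrix(gene.reshape(-1, 1), cells, ["G"])
        rec = dp.mutant_vs_wild_test(resp, mat, "G", "D")
        assert not rec.testable
        assert rec.mean_ic50_mut == pytest.approx(0.2)

    def test_welch_variant_runs_on_log_scale(self):
        rng = np.random.default_rng(2)
        cells = [f"c{i}" for i in range(30)]
        gene = np.r_[np.ones(15), np.zeros(15)]
        ic50 = np.r_[5 * rng.lognormal(0, 0.3, 15), rng.lognormal(0, 0.3, 15)]
        resp = dp.DrugResponseTable(pd.DataFrame({"D": ic50}, index=cells))
        mat = make_binary_matrix(gene.reshape(-1, 1), cells, ["G"])
        rec = dp.mutant_vs_wild_test(resp, mat, "G", "D", test="welch")
        assert 0 <= rec.p_value < 0.05


class TestTissueSummary:
    def test_all_sensitive_tissue_scores_100(self, tiny_response):
        # breast lines c3,c4 both ≤0.5 μM for drug B → 100% sensitive
        summary = dp.tissue_summary(tiny_response)
        assert summary.loc["breast", "B"] == pytest.approx(100.0)

    def test_no_sensitive_lines_scores_zero(self):
        cells = ["c1", "c2"]
        resp = dp.DrugResponseTable(
            pd.DataFrame({"A": [2.0, 3.0]}, index=cells),
            tissue={"c1": "lung", "c2": "lung"},
        )
        assert dp.tissue_summary(resp).loc["lung", "A"] == 0.0

    def test_matches_brute_force_per_tissue_tallies(self, small_dataset):
        resp = small_dataset.response
        summary = dp.tissue_summary(resp)
        for drug in resp.drugs:
            col = resp.ic50[drug].dropna()
            for tissue in summary.index:
                cells = [c for c in col.index if resp.tissue[c] == tissue]
                if not cells:
                    assert np.isnan(summary.loc[tissue, drug])
                    continue
                expected = 100.0 * sum(col[c] <= 0.5 for c in cells) / len(cells)
                assert summary.loc[tissue, drug] == pytest.approx(expected)


class TestDrugGroupBias:
    def test_singleton_class_equals_single_drug_bias(self, small_dataset):
        resp = small_dataset.response
        drug = resp.drugs[0]
        mat = small_dataset.matrices["mutation"]
        gene = mat.genes[3]
        labels = dp.classify_cells(resp, drug)
        single = dp.binary_bias(labels, mat, gene)
        pooled = dp.drug_group_bias(resp, mat, [drug], gene)
        assert (pooled.mut_res, pooled.n_res, pooled.mut_sen, pooled.n_sen) == (
            single.mut_res, single.n_res, single.mut_sen, single.n_sen)

    def test_identical_labels_pool_idempotently(self):
        cells = [f"c{i}" for i in range(8)]
        vals = [0.1, 0.2, 0.3, 0.4, 1.0, 2.0, 3.0, 4.0]
        resp = dp.DrugResponseTable(
            pd.DataFrame({"A": vals, "B": vals}, index=cells))
        rng = np.random.default_rng(3)
        mat = make_binary_matrix(
            rng.integers(0, 2, (8, 1)).astype(float), cells, ["G"])
        pooled = dp.drug_group_bias(resp, mat, ["A", "B"], "G")
        single = dp.drug_group_bias(resp, mat, ["A"], "G")
        assert pooled.f_res == pytest.approx(single.f_res)
        assert pooled.f_sen == pytest.approx(single.f_sen)

    def test_matches_brute_force_pair_pooling(self, small_dataset):
        resp = small_dataset.response
        drugs = resp.drugs[:3]
        mat = small_dataset.matrices["mutation"]
        gene = mat.genes[7]
        pooled = dp.drug_group_bias(resp, mat, drugs, gene)
        mut_res = n_res = mut_sen = n_sen = 0
        col = mat.values[gene]
        for d in drugs:
            ic50 = resp.ic50[d].dropna()
            for c in ic50.index:
                if c not in col.index:
                    continue
                if ic50[c] > 0.5:
                    n_res += 1
                    mut_res += int(col[c])
                else:
                    n_sen += 1
                    mut_sen += int(col[c])
        assert (pooled.mut_res, pooled.n_res, pooled.mut_sen, pooled.n_sen) == (
            mut_res, n_res, mut_sen, n_sen)

    def test_empty_class_rejected(self, small_dataset):
        with pytest.raises(dp.DataError):
            dp.drug_group_bias(
                small_dataset.response,
                small_dataset.matrices["mutation"], [], "MUT0000")
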