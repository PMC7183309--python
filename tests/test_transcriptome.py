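"""Expression normalization, DE calibration, clustering and trajectories."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dualscreen import (
    ExpressionTruth,
    ddct,
    de_gene_sets,
    de_summary,
    generate_expression_study,
    hierarchical_clusters,
    log2_cpm,
    log2fc_matrix,
    row_zscore,
    simple_de,
    trajectory_summary,
    transcriptome_correlation,
)
from dualscreen.transcriptome import benjamini_hochberg, read_de_table, write_de_table


def de_table(**cols):
    n = len(next(iter(cols.values())))
    base = {"gene": [f"g{i}" for i in range(n)]}
    base.update(cols)
    return pd.DataFrame(base)


class TestLog2Cpm:
    def test_zero_count_at_million_library(self):
        counts = pd.DataFrame({"s": [0, 999_999]}, index=["a", "b"])
        out = log2_cpm(counts)
        assert out.loc["a", "s"] == pytest.approx(math.log2(0.5), abs=1e-12)

    def test_formula_at_known_count(self):
        counts = pd.DataFrame({"s": [1023, 999_999 - 1023]}, index=["a", "b"])
        out = log2_cpm(counts)
        assert out.loc["a", "s"] == pytest.approx(math.log2(1023.5), abs=1e-12)

    def test_scale_invariance_for_large_counts(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame({"s": rng.integers(500, 5000, 100)})
        doubled = counts * 2
        diff = (log2_cpm(counts) - log2_cpm(doubled)).abs().to_numpy()
        assert diff.max() < 1e-3

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            log2_cpm(pd.DataFrame({"s": [-1, 2]}))


class TestBenjaminiHochberg:
    def test_step_up_by_hand(self):
        assert np.allclose(
            benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4
        )

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=200))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_brute_force_step_up(self, pvals):
        p = np.asarray(pvals)
        ours = benjamini_hochberg(p)
        # independent step-up: padj_(i) = min_{j >= i} min(1, m p_(j) / j)
        m = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.minimum(1.0, p[order] * m / np.arange(1, m + 1))
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = adj
        # implementations differ only in rounding order (p*m/i vs p/(i/m))
        assert np.allclose(ours, expected, rtol=1e-12, atol=0)
        assert np.all(ours >= p - 1e-15) and np.all(ours <= 1)


class TestSimpleDe:
    def _null_counts(self, seed, n_genes=400):
        counts, _ = generate_expression_study(
            n_genes, ["a", "b"], 3, ExpressionTruth(dispersion=0.05), seed=seed
        )
        return counts

    def test_identical_groups_give_unit_pvalues(self):
        counts = self._null_counts(0)
        dup = pd.concat(
            [counts[["a_r1", "a_r2", "a_r3"]]] * 2, axis=1
        )
        dup.columns = ["x1", "x2", "x3", "y1", "y2", "y3"]
        res = simple_de(dup, ["x1", "x2", "x3"], ["y1", "y2", "y3"])
        assert np.allclose(res.table["p"], 1.0)
        assert np.allclose(res.table["log2fc"], 0.0)

    def test_null_significant_fraction_small(self):
        fracs = [
            (simple_de(self._null_counts(s),
                       ["a_r1", "a_r2", "a_r3"],
                       ["b_r1", "b_r2", "b_r3"]).table["padj"] < 0.05).mean()
            for s in range(15)
        ]
        assert float(np.mean(fracs)) <= 0.07

    def test_planted_fold_changes_are_recovered(self):
        genes = [f"g{i:05d}" for i in range(500)]
        de = {g: 2.0 for g in genes[:25]} | {g: -2.0 for g in genes[25:50]}
        truth = ExpressionTruth(de_genes={"kd": de}, dispersion=0.05)
        counts, _ = generate_expression_study(500, ["c", "kd"], 3, truth, seed=1)
        res = simple_de(counts, [f"c_r{i}" for i in (1, 2, 3)],
                        [f"kd_r{i}" for i in (1, 2, 3)])
        tab = res.table.set_index("gene")
        sig = tab[tab["padj"] < 0.05]
        assert len(set(sig.index) & set(de)) / 50 >= 0.8
        assert np.sign(sig.loc[genes[0], "log2fc"]) == 1
        assert np.sign(sig.loc[genes[30], "log2fc"]) == -1

    def test_group_overlap_and_size_validation(self):
        counts = self._null_counts(2)
        with pytest.raises(ValueError, match="overlap"):
            simple_de(counts, ["a_r1", "a_r2"], ["a_r2", "b_r1"])
        with pytest.raises(ValueError, match="at least 2"):
            simple_de(counts, ["a_r1"], ["b_r1", "b_r2"])

    def test_all_zero_genes_excluded_and_reported(self):
        counts = self._null_counts(3).iloc[:20]
        counts.loc["dead"] = 0
        res = simple_de(counts, ["a_r1", "a_r2", "a_r3"], ["b_r1", "b_r2", "b_r3"])
        assert res.excluded_genes == ("dead",)
        assert "dead" not in set(res.table["gene"])


class TestDeGeneSets:
    def test_partition_by_direction_and_cutoff(self):
        tab = de_table(log2fc=[1.0, -1.0, 0.5], p=[0.001, 0.1, 0.001],
                       padj=[0.01, 0.2, 0.04])
        up, down, universe = de_gene_sets(tab, 0.05)
        assert up.members == {"G0", "G2"}
        assert down.members == set()
        assert universe.members == {"G0", "G1", "G2"}
        assert "G1" in universe.members

    def test_cutoff_is_strict(self):
        tab = de_table(log2fc=[1.0, 1.0], p=[0.01, 0.01], padj=[0.05, 0.049])
        up, _, _ = de_gene_sets(tab, 0.05)
        assert up.members == {"G1"}

    def test_alpha_domain_checked(self):
        tab = de_table(log2fc=[1.0], p=[0.01], padj=[0.01])
        for bad in (0.0, 1.0, -1, 2):
            with pytest.raises(ValueError):
                de_gene_sets(tab, bad)

    def test_up_down_disjoint_subsets_of_universe(self):
        rng = np.random.default_rng(4)
        tab = de_table(log2fc=rng.normal(size=300), p=rng.uniform(size=300),
                       padj=rng.uniform(size=300))
        up, down, universe = de_gene_sets(tab)
        assert not (up.members & down.members)
        assert up.members <= universe.members and down.members <= universe.members


class TestDeSummary:
    def test_fraction_up(self):
        tab = de_table(log2fc=[1.0] * 94 + [-1.0] * 6, p=[0.001] * 100,
                       padj=[0.001] * 100)
        s = de_summary(tab, 0.05)
        assert s.n_deregulated == 100 and s.fraction_up == pytest.approx(0.94)

    def test_mean_absolute_effect(self):
        tab = de_table(log2fc=[0.5, -0.5, 0.2], p=[0.01] * 3, padj=[0.01] * 3)
        assert de_summary(tab, 0.05).mean_abs_log2fc == pytest.approx(0.4)

    def test_empty_significant_set_reports_absent(self):
        tab = de_table(log2fc=[0.5], p=[0.9], padj=[0.9])
        s = de_summary(tab, 0.05)
        assert s.n_deregulated == 0
        assert s.fraction_up is None and s.mean_abs_log2fc is None


class TestLog2fcMatrix:
    def _tables(self):
        t1 = de_table(log2fc=[0.3], p=[0.01], padj=[0.01])
        t2 = de_table(log2fc=[-0.2], p=[0.01], padj=[0.01])
        return {"c1": t1, "c2": t2}

    def test_row_assembly(self):
        mat = log2fc_matrix(self._tables(), ["g0"])
        assert list(mat.loc["g0"]) == [0.3, -0.2]

    def test_fill_zero_policy_warns(self):
        tabs = self._tables()
        tabs["c2"] = de_table(log2fc=[0.1], p=[0.5], padj=[0.5]).assign(gene=["other"])
        with pytest.warns(UserWarning, match="filled"):
            mat = log2fc_matrix(tabs, ["g0"])
        assert mat.loc["g0", "c2"] == 0.0

    def test_drop_gene_policy(self):
        tabs = self._tables()
        tabs["c2"] = de_table(log2fc=[0.1], p=[0.5], padj=[0.5]).assign(gene=["other"])
        with pytest.warns(UserWarning, match="dropped"):
            mat = log2fc_matrix(tabs, ["g0"], policy="drop-gene")
        assert mat.empty


class TestRowZscore:
    def test_hand_computed_row(self):
        out = row_zscore(pd.DataFrame([[1.0, 2.0, 3.0]], index=["r"]))
        assert np.allclose(out.loc["r"], [-1, 0, 1])

    def test_constant_row_excluded_with_warning(self):
        m = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
        with pytest.warns(UserWarning, match="flat"):
            out = row_zscore(m)
        assert list(out.index) == ["ok"]

    def test_output_moments(self):
        rng = np.random.default_rng(5)
        out = row_zscore(pd.DataFrame(rng.normal(size=(30, 8))))
        assert np.abs(out.mean(axis=1)).max() < 1e-9
        assert np.abs(out.std(axis=1, ddof=1) - 1).max() < 1e-9


class TestTranscriptomeCorrelation:
    def test_identical_and_negated_columns(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=50)
        mat = pd.DataFrame({"a": v, "b": v, "c": -v})
        c = transcriptome_correlation(mat)
        assert c.get("a", "b") == pytest.approx(1.0)
        assert c.get("a", "c") == pytest.approx(-1.0)

    def test_matches_per_pair_oracle(self):
        rng = np.random.default_rng(7)
        mat = pd.DataFrame(rng.normal(size=(500, 10)),
                           columns=[f"k{i}" for i in range(10)])
        c = transcriptome_correlation(mat)
        x = mat.to_numpy()
        for i in range(10):
            for j in range(i + 1, 10):
                xi, xj = x[:, i] - x[:, i].mean(), x[:, j] - x[:, j].mean()
                r = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert abs(c.r[i, j] - r) < 1e-12

    def test_zero_variance_column_raises_with_name(self):
        mat = pd.DataFrame({"a": [1.0, 2.0, 3.0], "bad": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="bad"):
            transcriptome_correlation(mat)


class TestHierarchicalClusters:
    def test_separated_blobs_recovered(self):
        agreements = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 1, size=(20, 5))
            b = rng.normal(10, 1, size=(15, 5))
            labels = hierarchical_clusters(np.vstack([a, b]), k=2)
            # planted blob a is larger, so it must get label 1
            if (labels[:20] == 1).all() and (labels[20:] == 2).all():
                agreements += 1
        assert agreements >= 19

    def test_k_equals_rows_gives_singletons(self):
        rng = np.random.default_rng(8)
        labels = hierarchical_clusters(rng.normal(size=(6, 4)), k=6)
        assert sorted(labels) == [1, 2, 3, 4, 5, 6]

    def test_row_permutation_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(9)
        x = np.vstack([rng.normal(0, 1, (10, 4)), rng.normal(8, 1, (5, 4))])
        perm = rng.permutation(len(x))
        l1 = hierarchical_clusters(x, k=2)
        l2 = hierarchical_clusters(x[perm], k=2)
        assert np.array_equal(l1[perm], l2)

    def test_parameter_validation(self):
        x = np.zeros((3, 2))
        with pytest.raises(ValueError, match="exceeds"):
            hierarchical_clusters(np.random.default_rng(0).normal(size=(3, 2)), k=4)
        with pytest.raises(ValueError, match="ward"):
            hierarchical_clusters(x, k=2, metric="correlation", linkage="ward")


class TestTrajectorySummary:
    def test_single_gene_exact_normalization(self):
        expr = pd.DataFrame([[4.0, 2.0, 1.0]], index=["g"], columns=["t0", "t1", "t2"])
        traj = trajectory_summary(expr, n_boot=200, seed=0)
        assert np.allclose(traj.median, [1.0, 0.5, 0.25])
        assert np.allclose(traj.ci_low, traj.median)
        assert np.allclose(traj.ci_high, traj.median)

    def test_identical_genes_collapse_ci(self):
        expr = pd.DataFrame([[4.0, 2.0, 1.0]] * 10,
                            index=[f"g{i}" for i in range(10)],
                            columns=["t0", "t1", "t2"])
        traj = trajectory_summary(expr, n_boot=200, seed=0)
        assert np.allclose(traj.ci_high - traj.ci_low, 0.0)

    def test_each_gene_attains_its_maximum(self):
        rng = np.random.default_rng(10)
        expr = pd.DataFrame(rng.uniform(1, 9, size=(40, 5)))
        x = expr.to_numpy() / expr.to_numpy().max(axis=1, keepdims=True)
        assert np.allclose(x.max(axis=1), 1.0)
        traj = trajectory_summary(expr, n_boot=100, seed=0)
        assert np.all(traj.median > 0) and np.all(traj.median <= 1)
        assert np.all(traj.ci_low <= traj.median) and np.all(traj.median <= traj.ci_high)

    def test_non_positive_expression_rejected(self):
        expr = pd.DataFrame([[1.0, 0.0, 2.0]])
        with pytest.raises(ValueError, match="positive"):
            trajectory_summary(expr)


class TestDdct:
    def test_four_cycle_shift_quadruples(self):
        assert ddct(20, 15, 22, 15) == pytest.approx(4.0)

    def test_sample_equals_control(self):
        assert ddct(21, 15, 21, 15) == pytest.approx(1.0)

    def test_symmetric_shift_quarters(self):
        assert ddct(22, 15, 20, 15) == pytest.approx(0.25)


def test_de_table_tsv_round_trip_with_column_mapping(tmp_path):
    tab = de_table(log2fc=[0.5, -1.2], p=[0.01, 0.2], padj=[0.02, 0.4])
    path = tmp_path / "de.tsv"
    write_de_table(tab, path)
    back = read_de_table(path)
    pd.testing.assert_frame_equal(back, tab)
    external = tmp_path / "deseq_style.tsv"
    tab.rename(columns={"gene": "symbol", "log2fc": "log2FoldChange",
                        "p": "pvalue"}).to_csv(external, sep="\t", index=False)
    mapped = read_de_table(external, columns={"gene": "symbol",
                                              "log2fc": "log2FoldChange",
                                              "p": "pvalue", "padj": "padj"})
    pd.testing.assert_frame_equal(mapped, tab)
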