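import numpy as np
import pandas as pd
import pytest

from oracles import bh_stepup, complete_linkage_heights, venn_counts

from cperegnet.io import SampleSheet
from cperegnet.rip import (
    ContrastResults,
    RIPEnrichment,
    TargetSet,
    call_targets,
    cluster_targets,
    enrichment_heatmap_values,
    nb_test,
    overlap_sets,
    preferential_targets,
    shrink_lfc,
    size_factors,
)
from cperegnet.simulate import RIPTruth, gen_ripseq_counts
from cperegnet.stats import bh_adjust


def make_results(genes, lfc_shrunk, padj, contrast=("ip", "input")):
    table = pd.DataFrame(
        {
            "base_mean": 100.0,
            "log2fc": lfc_shrunk,
            "log2fc_shrunk": lfc_shrunk,
            "se": 0.1,
            "p": padj,
            "padj": padj,
            "tested": True,
        },
        index=pd.Index(genes, name="gene"),
    )
    return ContrastResults(contrast, table)


class TestSizeFactors:
    def test_equal_libraries_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_sample_has_double_factor(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf = size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_generator_library_sizes_recovered_within_5pct(self):
        truth = RIPTruth.planted(n_genes=2000, n_targets=0, seed=10)
        libs = {"input_r1": 1.5, "ni_ip_r2": 0.7}
        counts, _ = gen_ripseq_counts(truth, n_reps=3, lib_sizes=libs, seed=10)
        sf = size_factors(counts)
        rel = sf / sf["input_r2"]  # unit-library reference
        assert abs(rel["input_r1"] - 1.5) / 1.5 < 0.05
        assert abs(rel["ni_ip_r2"] - 0.7) / 0.7 < 0.05

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError):
            size_factors(counts)


class TestBH:
    def test_step_up_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = rng.random(int(rng.integers(1, 40)))
            assert np.allclose(bh_adjust(p), bh_stepup(p))

    def test_adjusted_monotone_in_p(self):
        rng = np.random.default_rng(1)
        p = rng.random(500)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestNBTest:
    def test_null_type_one_error_calibrated(self):
        truth = RIPTruth.planted(n_genes=2000, n_targets=0, seed=7)
        counts, sheet = gen_ripseq_counts(truth, n_reps=6, seed=7)
        res = nb_test(counts, sheet, ("cpeb1_ip", "input"))
        p = res.table["p"].dropna()
        assert 0.03 <= (p < 0.05).mean() <= 0.07

    def test_planted_lfc_recovered(self):
        truth = RIPTruth.planted(n_genes=2000, n_targets=150, lfc_ip=3.0, seed=1)
        counts, sheet = gen_ripseq_counts(truth, n_reps=6, seed=1)
        res = nb_test(counts, sheet, ("cpeb1_ip", "input"))
        targets = sorted(truth.targets("cpeb1_ip"))
        assert abs(res.table.loc[targets, "log2fc"].mean() - 3.0) < 0.3

    def test_all_zero_gene_excluded_padj_absent(self):
        truth = RIPTruth.planted(n_genes=200, n_targets=0, seed=2)
        counts, sheet = gen_ripseq_counts(truth, n_reps=3, seed=2)
        gene = counts.index[0]
        counts.loc[gene] = 0
        res = nb_test(counts, sheet, ("cpeb1_ip", "input"))
        assert np.isnan(res.table.loc[gene, "padj"])

    def test_absent_condition_errors(self):
        truth = RIPTruth.planted(n_genes=50, n_targets=0, seed=3)
        counts, sheet = gen_ripseq_counts(truth, n_reps=2, seed=3)
        with pytest.raises(ValueError, match="cpeb9"):
            nb_test(counts, sheet, ("cpeb9_ip", "input"))

    def test_single_replicate_rejected(self):
        counts = pd.DataFrame(
            {"input_r1": [5, 8], "input_r2": [6, 9], "ip_r1": [7, 10]},
            index=["g1", "g2"],
        )
        sheet = SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": ["input_r1", "input_r2", "ip_r1"],
                    "condition": ["input", "input", "ip"],
                    "replicate": [1, 2, 1],
                }
            )
        )
        with pytest.raises(ValueError, match="<2 replicates"):
            nb_test(counts, sheet, ("ip", "input"))

    def test_scale_invariance_under_size_factor(self):
        truth = RIPTruth.planted(n_genes=300, n_targets=30, seed=4)
        counts, sheet = gen_ripseq_counts(truth, n_reps=3, seed=4)
        sf = pd.Series(1.0, index=counts.columns)
        res1 = nb_test(counts, sheet, ("cpeb1_ip", "input"), sf=sf, min_total_count=0)
        scaled = counts.copy()
        scaled["input_r1"] = (scaled["input_r1"] * 4).astype(int)
        sf2 = sf.copy()
        sf2["input_r1"] = 4.0
        res2 = nb_test(scaled, sheet, ("cpeb1_ip", "input"), sf=sf2, min_total_count=0)
        assert np.allclose(res1.table["stat"], res2.table["stat"], equal_nan=True)


class TestShrinkLFC:
    def _table(self, lfc, se):
        return pd.DataFrame(
            {"base_mean": 100.0, "log2fc": lfc, "se": se, "tested": True}
        )

    def test_zero_se_keeps_raw(self):
        t = shrink_lfc(self._table([4.0], [0.0]), prior_sd=1.0)
        assert t["log2fc_shrunk"].iloc[0] == pytest.approx(4.0)

    def test_huge_se_shrinks_to_zero(self):
        t = shrink_lfc(self._table([4.0], [100.0]), prior_sd=1.0)
        assert abs(t["log2fc_shrunk"].iloc[0]) < 0.01

    def test_noisier_gene_shrinks_strictly_more(self):
        t = shrink_lfc(self._table([3.0, 3.0], [0.1, 1.0]), prior_sd=1.0)
        s = t["log2fc_shrunk"]
        assert abs(s.iloc[1]) < abs(s.iloc[0]) <= 3.0
        assert (np.sign(s) == 1).all()


class TestCallTargets:
    def test_threshold_logic(self):
        genes = ["g1", "g2", "g3"]
        #      8x sig       8x sig        8x not-sig
        res_in = make_results(genes, [3.0, 3.0, 3.0], [0.01, 0.01, 0.2])
        #      3x sig       1.5x sig      3x sig
        res_ni = make_results(genes, [np.log2(3), np.log2(1.5), 2.0], [0.01, 0.01, 0.01])
        ts = call_targets(res_in, res_ni)
        assert set(ts.genes) == {"g1"}

    def test_mismatched_universe_errors(self):
        res_in = make_results(["g1"], [3.0], [0.01])
        res_ni = make_results(["g2"], [3.0], [0.01])
        with pytest.raises(ValueError):
            call_targets(res_in, res_ni)

    def test_planted_recovery_sensitivity_and_fdr(self):
        truth = RIPTruth.planted(n_genes=800, n_targets=60, seed=5)
        counts, sheet = gen_ripseq_counts(truth, n_reps=6, seed=5)
        results = RIPEnrichment(counts, sheet).fit()
        called = set(results.targets["cpeb1_ip"].genes)
        true = truth.targets("cpeb1_ip")
        assert len(called & true) / len(true) >= 0.8
        assert len(called - true) / max(len(called), 1) <= 0.1


class TestPreferential:
    def test_rule_application(self):
        genes = ["a", "b", "c"]
        null = make_results(genes, [0.0, 0.0, 0.0], [0.9, 0.9, 0.9])
        res = {
            "cpeb2_ip": make_results(genes, [3.0, 0.0, -3.0], [0.001, 0.9, 0.001]),
            "cpeb3_ip": null,
            "cpeb4_ip": null,
        }
        c1, c24, shared = preferential_targets(set(genes), res)
        assert c1 == {"a"} and c24 == {"c"} and shared == {"b"}

    def test_sets_partition_the_union(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(50)]
        res = {
            x: make_results(genes, rng.normal(0, 2.5, 50), rng.random(50) * 0.1)
            for x in ("cpeb2_ip", "cpeb3_ip", "cpeb4_ip")
        }
        union = set(genes)
        c1, c24, shared = preferential_targets(union, res)
        assert c1 | c24 | shared == union
        assert not (c1 & c24) and not (c1 & shared) and not (c24 & shared)

    def test_three_class_simulation_recovery(self):
        truth = RIPTruth.three_class(n_genes=1200, n_per_class=40, seed=8)
        counts, sheet = gen_ripseq_counts(truth, n_reps=6, seed=8)
        results = RIPEnrichment(counts, sheet).fit()
        c1, c24, shared = results.preferential(lfc_thresh=2.0)
        labels = truth.class_labels
        union = results.union_targets
        for called, key in ((c1, "cpeb1_pref"), (c24, "cpeb24_pref"), (shared, "shared")):
            true_in_union = labels[key] & union
            assert len(true_in_union) > 0
            assert len(called & true_in_union) / len(true_in_union) >= 0.8, key


class TestOverlap:
    def _ts(self, name, genes):
        return TargetSet(name, frozenset(genes))

    def test_identical_sets_center_cell_only(self):
        genes = {f"g{i}" for i in range(10)}
        sets = {c: self._ts(c, genes) for c in "1234"}
        table = overlap_sets(sets)
        assert table.loc[table["degree"] == 4, "count"].iloc[0] == 10
        assert table["count"].sum() == 10

    def test_disjoint_sets_singletons_only(self):
        sets = {c: self._ts(c, {f"{c}_{i}" for i in range(3)}) for c in "1234"}
        table = overlap_sets(sets)
        assert (table["degree"] == 1).all()
        assert table["count"].sum() == 12

    def test_random_sets_match_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        universe = [f"g{i}" for i in range(200)]
        raw = {c: set(rng.choice(universe, 80, replace=False)) for c in "1234"}
        table = overlap_sets({c: self._ts(c, s) for c, s in raw.items()})
        got = {
            frozenset(row.combination.split("&")): row.count
            for row in table.itertuples()
        }
        assert got == venn_counts(raw)
        assert table["count"].sum() == len(set().union(*raw.values()))


class TestHeatmapAndClustering:
    def test_score_is_euclidean_norm_of_centered_fcs(self):
        genes = ["a", "b"]
        res_in = {"c1": make_results(genes, [3.0, -3.0], [0.01, 0.01])}
        res_ni = {"c1": make_results(genes, [4.0, -4.0], [0.01, 0.01])}
        heat = enrichment_heatmap_values(res_in, res_ni, genes)
        assert np.allclose(heat["c1"], [5.0, 5.0])

    def test_identical_genes_merge_at_height_zero(self):
        m = pd.DataFrame(np.ones((5, 2)), index=[f"g{i}" for i in range(5)])
        Z, newick = cluster_targets(m)
        assert np.allclose(Z[:, 2], 0.0)
        assert newick.endswith(";")

    def test_two_blob_heights_match_brute_force(self):
        rng = np.random.default_rng(9)
        pts = np.vstack([rng.normal(0, 0.2, (6, 2)), rng.normal(5, 0.2, (6, 2))])
        m = pd.DataFrame(pts, index=[f"g{i}" for i in range(12)])
        Z, _ = cluster_targets(m)
        assert np.allclose(sorted(Z[:, 2]), sorted(complete_linkage_heights(pts)))
        assert (np.diff(Z[:, 2]) >= -1e-12).all()  # monotone merge heights
        # top split separates the blobs
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(Z, 2, criterion="maxclust")
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[6]
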