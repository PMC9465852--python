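import numpy as np
import pandas as pd
import pytest

from cperegnet.bioid import (
    ProximomeAnalysis,
    knn_impute,
    moderated_test,
    percentile_normalize,
    rank_compare,
    rescue_rule,
)
from cperegnet.io import SampleSheet
from cperegnet.simulate import BioIDTruth, gen_bioid_matrix


@pytest.fixture
def sheet44():
    return SampleSheet.from_conditions({"birA_control": 4, "cpeb_birA": 4})


def matrix_from(values, sheet, prefix="p"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=pd.Index([f"{prefix}{i}" for i in range(len(values))], name="protein"),
        columns=sheet.sample_ids,
    )


class TestPercentileNormalize:
    def test_affine_sample_maps_to_identical_column(self):
        rng = np.random.default_rng(1)
        a = rng.normal(7, 1, 50)
        m = pd.DataFrame({"s1": a, "s2": 2.0 * a + 3.0})
        out = percentile_normalize(m)
        assert np.allclose(out["s1"], out["s2"])

    def test_equal_missingness_gives_identical_sorted_columns(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(7, 1, (60, 4)), columns=list("abcd"))
        m.iloc[:5, :] = np.nan  # same number missing per sample
        out = percentile_normalize(m)
        cols = [np.sort(out[c].dropna().to_numpy()) for c in out]
        for c in cols[1:]:
            assert np.allclose(cols[0], c)

    def test_missing_cells_stay_missing_and_order_preserved(self):
        m = pd.DataFrame({"s1": [5.0, np.nan, 7.0, 6.0], "s2": [1.0, 2.0, 3.0, 4.0]})
        out = percentile_normalize(m)
        assert np.isnan(out.loc[1, "s1"])
        assert out.loc[2, "s1"] > out.loc[3, "s1"] > out.loc[0, "s1"]

    def test_sample_with_fewer_than_two_values_rejected(self):
        m = pd.DataFrame({"s1": [5.0, np.nan], "s2": [1.0, 2.0]})
        with pytest.raises(ValueError, match="s1"):
            percentile_normalize(m)


class TestKnnImpute:
    def test_complete_rows_bitwise_unchanged(self, sheet44):
        rng = np.random.default_rng(3)
        m = matrix_from(rng.normal(7, 1, (30, 8)), sheet44)
        out = knn_impute(m)
        pd.testing.assert_frame_equal(out, m)

    def test_rows_with_three_missing_untouched(self, sheet44):
        rng = np.random.default_rng(4)
        vals = rng.normal(7, 1, (30, 8))
        vals[0, :3] = np.nan
        m = matrix_from(vals, sheet44)
        out = knn_impute(m, max_missing=2)
        assert out.iloc[0].isna().sum() == 3

    def test_constant_matrix_hole_filled_with_constant(self, sheet44):
        vals = np.full((15, 8), 5.0)
        vals[2, 1] = np.nan
        out = knn_impute(matrix_from(vals, sheet44))
        assert out.iloc[2, 1] == pytest.approx(5.0)

    def test_only_missing_cells_of_imputable_rows_altered(self, sheet44):
        rng = np.random.default_rng(5)
        vals = rng.normal(7, 1, (40, 8))
        vals[vals < 6.2] = np.nan
        m = matrix_from(vals, sheet44)
        out = knn_impute(m)
        present = ~m.isna()
        diff = (out - m).to_numpy()
        assert np.nansum(np.abs(diff[present.to_numpy()])) == 0.0
        n_missing = m.isna().sum(axis=1)
        untouched = m[(n_missing == 0) | (n_missing > 2)]
        pd.testing.assert_frame_equal(out.loc[untouched.index], untouched)

    def test_fewer_donors_than_k_warns(self, sheet44):
        vals = np.full((3, 8), 4.0)
        vals[0, 0] = np.nan
        with pytest.warns(UserWarning, match="donor"):
            out = knn_impute(matrix_from(vals, sheet44), k=10)
        assert out.iloc[0, 0] == pytest.approx(4.0)


class TestRescueRule:
    def _matrix(self, ctrl, cond, sheet, n_background=40, seed=0):
        rng = np.random.default_rng(seed)
        bg = rng.normal(7, 1, (n_background, 8))
        vals = np.vstack([np.array(ctrl + cond, dtype=float), bg])
        return matrix_from(vals, sheet)

    def test_fully_missing_control_abundant_condition_rescued(self, sheet44):
        m = self._matrix([np.nan] * 4, [8.0, 8.1, 7.9, 8.0], sheet44)
        ok, pct = rescue_rule(m, sheet44, "p0")
        assert ok and pct > 25

    def test_two_missing_in_control_not_rescued(self, sheet44):
        m = self._matrix([np.nan, np.nan, 7.0, 7.1], [8.0, 8.1, 7.9, 8.0], sheet44)
        ok, _ = rescue_rule(m, sheet44, "p0")
        assert not ok

    def test_two_missing_in_condition_not_rescued(self, sheet44):
        m = self._matrix([np.nan] * 4, [8.0, 8.1, np.nan, np.nan], sheet44)
        ok, _ = rescue_rule(m, sheet44, "p0")
        assert not ok

    def test_low_abundance_condition_not_rescued(self, sheet44):
        m = self._matrix([np.nan] * 4, [4.0, 4.1, 3.9, 4.0], sheet44)
        ok, pct = rescue_rule(m, sheet44, "p0")
        assert not ok and pct < 25


class TestModeratedTest:
    def test_null_type_one_error_calibrated(self, sheet44):
        rng = np.random.default_rng(6)
        m = matrix_from(rng.normal(7, 0.25, (1000, 8)), sheet44)
        res = moderated_test(m, sheet44)
        assert 0.03 <= (res["p"] < 0.05).mean() <= 0.07

    def test_planted_hits_recovered(self, sheet44):
        rng = np.random.default_rng(7)
        vals = rng.normal(7, 0.25, (1000, 8))
        vals[:30, 4:] += 1.0  # +1.0 log10 shift in the condition samples
        m = matrix_from(vals, sheet44)
        res = moderated_test(m, sheet44)
        called = set(res.index[(res["padj"] < 0.05) & (res["log2fc"] > 0)])
        true = {f"p{i}" for i in range(30)}
        assert len(called & true) / 30 >= 0.8
        assert len(called - true) / max(len(called), 1) <= 0.1

    def test_equal_effect_equal_variance_equal_t(self, sheet44):
        row = [5.0, 6.0, 5.0, 6.0, 7.0, 8.0, 7.0, 8.0]
        m = matrix_from([row, row], sheet44)
        res = moderated_test(m, sheet44)
        assert res["t"].iloc[0] == pytest.approx(res["t"].iloc[1])

    def test_log2fc_conversion_from_log10(self, sheet44):
        vals = np.tile([7.0] * 4 + [7.0 + np.log10(2)] * 4, (20, 1))
        m = matrix_from(vals + np.random.default_rng(8).normal(0, 0.01, vals.shape), sheet44)
        res = moderated_test(m, sheet44)
        assert res["log2fc"].mean() == pytest.approx(1.0, abs=0.05)


class TestCallProximome:
    def test_planted_recovery_both_routes(self):
        truth = BioIDTruth.default(seed=3)
        matrix, sheet = gen_bioid_matrix(truth, seed=3)
        res = ProximomeAnalysis(matrix, sheet).fit()
        called = set(res.hits.index)
        true = truth.hits
        assert len(called & true) / len(true) >= 0.8
        assert len(called - true) / max(len(called), 1) <= 0.1
        routes = set(res.hits["route"])
        assert routes == {"tested", "rescued"}

    def test_routes_mutually_exclusive(self):
        truth = BioIDTruth.default(n_proteins=300, seed=4)
        matrix, sheet = gen_bioid_matrix(truth, seed=4)
        res = ProximomeAnalysis(matrix, sheet).fit()
        tested = res.table["route"] == "tested"
        rescued = res.table["route"] == "rescued"
        assert not (tested & rescued).any()

    def test_null_matrix_rarely_yields_hits(self):
        truth = BioIDTruth.default(n_tested_hits=0, n_rescued_hits=0, n_proteins=500, seed=5)
        matrix, sheet = gen_bioid_matrix(truth, seed=5)
        res = ProximomeAnalysis(matrix, sheet).fit()
        assert res.table["hit"].sum() <= 2

    def test_deterministic_given_matrix(self):
        truth = BioIDTruth.default(n_proteins=200, seed=6)
        matrix, sheet = gen_bioid_matrix(truth, seed=6)
        r1 = ProximomeAnalysis(matrix, sheet).fit().table
        r2 = ProximomeAnalysis(matrix, sheet).fit().table
        pd.testing.assert_frame_equal(r1, r2)


class TestRankCompare:
    def test_identical_lists_zero_delta(self):
        s = pd.Series([5.0, 3.0, 1.0], index=["a", "b", "c"])
        out = rank_compare(s, s)
        assert (out["delta"] == 0).all()

    def test_absent_protein_ranked_last_plus_one(self):
        a = pd.Series([5.0, 3.0], index=["x", "y"])
        b = pd.Series([5.0], index=["x"])
        out = rank_compare(a, b)
        assert out.loc["y", "rank_b"] == 2  # last (1) + 1

    def test_dense_ranks_share_draws(self):
        s = pd.Series([5.0, 5.0, 3.0], index=["a", "b", "c"])
        out = rank_compare(s, s)
        assert list(out.loc[["a", "b", "c"], "rank_a"]) == [1, 1, 2]
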