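import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bimaxgsea import (
    DoseResponseStudy,
    dose_f_statistics,
    enrich_all,
    geneset_welch_test,
    welch_t,
)


def make_dose_study(values, groups, study_id="S"):
    values = pd.DataFrame(values)
    values.columns = [f"s{i}" for i in range(values.shape[1])]
    dose = pd.Series(list(groups), index=values.columns)
    return DoseResponseStudy(study_id=study_id, values=values, dose_group=dose)


class TestDoseFStatistics:
    def test_hand_worked_anova_decomposition(self):
        # groups {1,2,3}, {2,3,4}, {3,4,5}: MSB = 3, MSW = 1 -> F = 3
        study = make_dose_study(
            [[1, 2, 3, 2, 3, 4, 3, 4, 5]], "aaabbbccc"
        )
        fs = dose_f_statistics(study)
        assert fs.table["F"].iloc[0] == pytest.approx(3.0, abs=1e-12)
        assert fs.table["log2_f"].iloc[0] == pytest.approx(np.log2(3.0))

    def test_equal_group_means_give_zero_f_flagged(self):
        study = make_dose_study([[1, 3, 1, 3, 1, 3]], "aabbcc")
        fs = dose_f_statistics(study)
        assert fs.table["F"].iloc[0] == 0.0
        assert not fs.table["defined"].iloc[0]
        assert fs.table["status"].iloc[0] == "zero_f"

    def test_constant_gene_flagged_undefined(self):
        study = make_dose_study([[2.0] * 6], "aabbcc")
        fs = dose_f_statistics(study)
        assert np.isnan(fs.table["F"].iloc[0])
        assert fs.table["status"].iloc[0] == "zero_within_variance"

    def test_small_dose_level_is_named(self):
        values = pd.DataFrame([[1, 2, 3, 4, 5]], columns=[f"s{i}" for i in range(5)])
        dose = pd.Series(["a", "a", "b", "b", "tiny"], index=values.columns)
        with pytest.raises(ValueError, match="tiny"):
            DoseResponseStudy(study_id="S", values=values, dose_group=dose)

    def test_matches_scipy_reference_anova(self, rng):
        data = rng.normal(size=(100, 12))
        groups = "aaa" + "bbb" + "ccc" + "ddd"
        study = make_dose_study(data, groups)
        fs = dose_f_statistics(study)
        for i in range(100):
            ref = stats.f_oneway(
                data[i, :3], data[i, 3:6], data[i, 6:9], data[i, 9:12]
            ).statistic
            assert fs.table["F"].iloc[i] == pytest.approx(ref, rel=1e-10)

    def test_scale_invariance(self, rng):
        data = rng.normal(size=(20, 9))
        a = dose_f_statistics(make_dose_study(data, "aaabbbccc"))
        b = dose_f_statistics(make_dose_study(data + 7.3, "aaabbbccc"))
        pd.testing.assert_series_equal(a.table["F"], b.table["F"], atol=1e-9)


class TestWelch:
    def test_hand_worked_example(self):
        t, df = welch_t([1, 2, 3], [2, 4, 6])
        assert t == pytest.approx(-1.549, abs=5e-4)
        assert df == pytest.approx(2.94, abs=5e-3)

    def test_matches_scipy_reference(self, rng):
        for _ in range(100):
            x = rng.normal(size=rng.integers(3, 30))
            y = rng.normal(scale=rng.uniform(0.5, 3), size=rng.integers(3, 30))
            t, df = welch_t(x, y)
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            assert df == pytest.approx(ref.df, rel=1e-10)


class TestGenesetWelchTest:
    def _fstats(self, rng, n=200):
        data = rng.normal(size=(n, 12))
        groups = "aaabbbcccddd"
        study = make_dose_study(data, groups)
        study.values.index = [f"G{i}" for i in range(n)]
        return dose_f_statistics(study)

    def test_set_equal_to_all_genes_gives_t_zero(self, rng):
        fs = self._fstats(rng)
        res = geneset_welch_test(fs, fs.usable.index)
        assert res.t_statistic == 0.0
        assert res.p_value == 1.0

    def test_undersized_set_flagged_not_evaluable(self, rng):
        fs = self._fstats(rng)
        res = geneset_welch_test(fs, ["G0"])
        assert not res.evaluable
        assert np.isnan(res.p_value)

    def test_p_value_consistent_with_t_and_df(self, rng):
        fs = self._fstats(rng)
        res = geneset_welch_test(fs, [f"G{i}" for i in range(20)])
        expected = 2 * stats.t.sf(abs(res.t_statistic), res.degrees_of_freedom)
        assert res.p_value == pytest.approx(expected, rel=1e-12)
        assert res.n_set <= res.n_background

    def test_complement_background_excludes_set(self, rng):
        fs = self._fstats(rng)
        genes = [f"G{i}" for i in range(20)]
        res = geneset_welch_test(fs, genes, background="complement")
        assert res.n_background == len(fs.usable) - res.n_set

    def test_scale_invariance_of_t_and_p(self, rng):
        data = rng.normal(size=(100, 12))
        genes = [f"G{i}" for i in range(100)]
        out = []
        for shift in (0.0, 5.0):
            study = make_dose_study(data + shift, "aaabbbcccddd")
            study.values.index = genes
            fs = dose_f_statistics(study)
            out.append(geneset_welch_test(fs, genes[:15]))
        assert out[0].t_statistic == pytest.approx(out[1].t_statistic, rel=1e-9)
        assert out[0].p_value == pytest.approx(out[1].p_value, rel=1e-9)


class TestEnrichAll:
    def _studies(self, rng, n_studies=3):
        out = []
        for k in range(n_studies):
            data = rng.normal(size=(50, 12))
            study = make_dose_study(data, "aaabbbcccddd", study_id=f"S{k}")
            study.values.index = [f"G{i}" for i in range(50)]
            out.append(study)
        return out

    def test_full_cross_product_of_results(self, rng):
        studies = self._studies(rng)
        sets = {f"set{j}": [f"G{i}" for i in range(j, j + 10)] for j in range(10)}
        long, matrix = enrich_all(studies, sets)
        assert len(long) == 30
        assert matrix.shape == (10, 3)

    def test_bh_adjustment_monotone_in_rank(self, rng):
        studies = self._studies(rng, 1)
        sets = {f"set{j}": [f"G{i}" for i in range(j, j + 10)] for j in range(10)}
        long, _ = enrich_all(studies, sets, adjust="BH")
        sub = long.sort_values("p")
        assert sub["p_adj"].is_monotonic_increasing
        assert (sub["p_adj"] >= sub["p"] - 1e-15).all()

    def test_single_pair_matches_direct_test(self, rng):
        studies = self._studies(rng, 1)
        from bimaxgsea import dose_f_statistics as dfs

        genes = [f"G{i}" for i in range(10)]
        long, _ = enrich_all(studies, {"s": genes})
        direct = geneset_welch_test(dfs(studies[0]), genes, set_name="s")
        assert long.loc[0, "t"] == pytest.approx(direct.t_statistic)
        assert long.loc[0, "p"] == pytest.approx(direct.p_value)
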