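import numpy as np
import pandas as pd
import pytest
from scipy import stats

from voxelprot.qc import eligibility_table
from voxelprot.rollup import rrollup
from voxelprot.stats import anova_tukey, compare_groups, g_statistic, gtest_holm, holm

from conftest import make_metadata
from oracles import g_via_loglik, studentized_range_sf
from test_qc import protein_matrix


class TestAnovaTukey:
    def test_identical_constant_groups_give_p_one(self):
        res = anova_tukey({"A": [3.0, 3.0], "B": [3.0, 3.0], "C": [3.0, 3.0]})
        assert (res["p_tukey"] == 1.0).all()

    def test_balanced_fixture_matches_quadrature_oracle(self):
        res = anova_tukey(
            {"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0], "C": [6.0, 7.0, 8.0]}
        ).set_index(["pair_a", "pair_b"])
        assert res.loc[("A", "B"), "p_tukey"] == pytest.approx(1.0, abs=1e-12)
        # oracle value frozen from the independent double-quadrature
        # computation at q = 5 * sqrt(3), k = 3, df = 6
        assert res.loc[("A", "C"), "p_tukey"] == pytest.approx(2.10124058e-3, rel=1e-6)
        assert res.loc[("B", "C"), "p_tukey"] == pytest.approx(2.10124058e-3, rel=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_fixtures_match_quadrature_oracle(self, seed):
        rng = np.random.default_rng(seed)
        groups = {g: rng.normal(rng.uniform(-1, 1), 1, rng.integers(3, 7)) for g in "ABC"}
        res = anova_tukey(groups)
        n = {g: len(v) for g, v in groups.items()}
        mean = {g: np.mean(v) for g, v in groups.items()}
        df = sum(n.values()) - 3
        s2 = sum(((np.asarray(v) - mean[g]) ** 2).sum() for g, v in groups.items()) / df
        for _, row in res.iterrows():
            a, b = row["pair_a"], row["pair_b"]
            q = abs(mean[a] - mean[b]) / np.sqrt(s2 / 2 * (1 / n[a] + 1 / n[b]))
            assert row["p_tukey"] == pytest.approx(studentized_range_sf(q, 3, df), rel=1e-6)

    def test_scale_invariance(self):
        g1 = {"A": [1.0, 2.0, 3.0], "B": [2.0, 3.0, 5.0], "C": [6.0, 7.0, 8.0]}
        g2 = {k: [2 * x for x in v] for k, v in g1.items()}
        r1 = anova_tukey(g1)["p_tukey"].to_numpy()
        r2 = anova_tukey(g2)["p_tukey"].to_numpy()
        np.testing.assert_allclose(r1, r2, rtol=1e-10)

    def test_two_groups_reduce_to_pooled_t_test(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 5), rng.normal(1, 1, 6)
        res = anova_tukey({"A": list(a), "B": list(b)})
        t_p = stats.ttest_ind(a, b).pvalue
        assert res["p_tukey"].iloc[0] == pytest.approx(t_p, rel=1e-8)
        assert res["p_raw"].iloc[0] == pytest.approx(t_p, rel=1e-10)

    def test_exact_separation_clamped_at_machine_epsilon(self):
        res = anova_tukey({"A": [1.0, 1.0], "B": [2.0, 2.0]})
        assert res["p_tukey"].iloc[0] == np.finfo(float).eps

    def test_group_with_one_value_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_tukey({"A": [1.0], "B": [1.0, 2.0]})


class TestGTest:
    def test_equal_proportions_give_zero_g(self):
        assert g_statistic(3, 5, 3, 5) == pytest.approx(0.0)
        res = gtest_holm({("A", "B"): (3, 5, 3, 5)})
        assert res["p_raw"].iloc[0] == 1.0

    def test_complete_separation_value(self):
        # 5/5 observed vs 0/5 observed: G = 20 ln 2
        assert g_statistic(5, 5, 0, 5) == pytest.approx(20 * np.log(2))

    @pytest.mark.parametrize("seed", range(5))
    def test_g_equals_loglik_ratio_oracle(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(2, 10, 2)
        oa, ob = rng.integers(0, na + 1), rng.integers(0, nb + 1)
        table = np.array([[oa, ob], [na - oa, nb - ob]])
        if table.sum(axis=1).min() == 0:
            pytest.skip("degenerate margin")
        assert g_statistic(oa, na, ob, nb) == pytest.approx(g_via_loglik(table))

    def test_zero_group_raises(self):
        with pytest.raises(ValueError):
            g_statistic(0, 0, 1, 5)


class TestHolm:
    def test_printed_triple(self):
        np.testing.assert_allclose(
            holm(np.array([0.01, 0.04, 0.2])), [0.03, 0.08, 0.2]
        )

    def test_monotone_in_raw_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=20)
        adj = holm(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_never_below_raw_never_above_one(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=15)
        adj = holm(p)
        assert (adj >= p).all() and (adj <= 1.0).all()


class TestCompareGroups:
    def setup_method(self):
        self.meta = make_metadata({"A": 5, "B": 5, "C": 5})

    def test_identical_distributions_not_significant(self):
        vals = list(np.tile([1.0, 2.0, 3.0, 4.0, 5.0], 3))
        prot = protein_matrix({"P": vals}, self.meta.sample_ids)
        summary = compare_groups(prot, self.meta, eligibility_table(prot, self.meta))
        assert not summary.results["significant"].any()
        assert (summary.results["direction"] == "none").all()

    def test_direction_follows_mean_difference(self):
        vals = [10.0, 10.1, 9.9, 10.05, 9.95] + [5.0, 5.1, 4.9, 5.05, 4.95] + [5.0, 5.2, 4.8, 5.1, 4.9]
        prot = protein_matrix({"P": vals}, self.meta.sample_ids)
        summary = compare_groups(prot, self.meta, eligibility_table(prot, self.meta))
        r = summary.results.set_index("pair")
        assert bool(r.loc["A|B", "significant"])
        assert r.loc["A|B", "direction"] == "up_in_A"
        assert r.loc["B|C", "direction"] == "none"

    def test_qualitative_pair_routed_to_gtest(self):
        vals = [10.0, 10.1, 9.9, 10.05, 9.95] + [np.nan] * 5 + [10.0, 10.2, 9.8, 10.1, 9.9]
        prot = protein_matrix({"P": vals}, self.meta.sample_ids)
        summary = compare_groups(prot, self.meta, eligibility_table(prot, self.meta))
        r = summary.results.set_index("pair")
        assert r.loc["A|B", "test"] == "gtest"
        assert r.loc["A|C", "test"] == "anova"
        # 5/5 observed vs 0/5: G = 20 ln 2, chi2 p ~ 1.97e-4, Holm x2 across
        # the protein's two qualitative pairs is still < 0.05
        assert bool(r.loc["A|B", "significant"])
        assert r.loc["A|B", "direction"] == "up_in_A"

    def test_strong_effect_detected_with_seeded_simulation(self):
        rng = np.random.default_rng(42)
        vals = list(rng.normal(22.0, 0.25, 5)) + list(rng.normal(20.0, 0.25, 5)) + list(
            rng.normal(20.0, 0.25, 5)
        )
        prot = protein_matrix({"P": vals}, self.meta.sample_ids)
        summary = compare_groups(prot, self.meta, eligibility_table(prot, self.meta))
        r = summary.results.set_index("pair")
        assert bool(r.loc["A|B", "significant"]) and r.loc["A|B", "direction"] == "up_in_A"
        assert bool(r.loc["A|C", "significant"])

    def test_counts_match_results_table(self, pools_dataset):
        prot = rrollup(pools_dataset.peptides)
        summary = compare_groups(
            prot, pools_dataset.metadata, eligibility_table(prot, pools_dataset.metadata)
        )
        recount = (
            summary.results[summary.results["significant"]]
            .groupby(["pair", "test", "direction"])
            .size()
        )
        for _, row in summary.counts.iterrows():
            assert recount[(row["pair"], row["test"], row["direction"])] == row["n_significant"]
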