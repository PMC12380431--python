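import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spotrank import (
    GroupSummary,
    SimulationConfig,
    call_hits,
    compute_fcs,
    compute_sns,
    holm_sidak_adjust,
    ks_two_sample,
    permutation_test,
    score_genes,
    simulate_visium_dataset,
    ttest_from_summary,
    ttest_two_sample,
)

finite = st.floats(-50, 50)
positive = st.floats(0.1, 50)
pvals = st.floats(1e-10, 1.0)


class TestTTests:
    def test_equal_samples_give_null(self):
        res = ttest_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_pooled_hand_value(self):
        # exact summary-matched samples: mean 1 vs 0, sd 1, n 10 each
        a = GroupSummary(1.0, 1.0, 10)
        b = GroupSummary(0.0, 1.0, 10)
        res = ttest_from_summary(a, b, "student_pooled")
        assert res.statistic == pytest.approx(2.2361, abs=1e-4)
        assert res.df == 18
        assert res.p_value == pytest.approx(0.0382, abs=5e-4)

    def test_summary_matches_raw_data(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(1, 2, 12), rng.normal(0, 1, 9)
        raw = ttest_two_sample(a, b, "student_pooled")
        summ = ttest_from_summary(
            GroupSummary.from_values(a), GroupSummary.from_values(b), "student_pooled"
        )
        assert abs(raw.statistic - summ.statistic) < 1e-12
        assert abs(raw.p_value - summ.p_value) < 1e-12

    def test_welch_matches_raw_data(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(1, 3, 8), rng.normal(0, 1, 20)
        raw = ttest_two_sample(a, b, "welch")
        summ = ttest_from_summary(
            GroupSummary.from_values(a), GroupSummary.from_values(b), "welch"
        )
        assert abs(raw.p_value - summ.p_value) < 1e-12

    def test_sem_kind_converted(self):
        sd = GroupSummary(4.9, 2.9 * math.sqrt(5), 5, kind="SD")
        sem = GroupSummary(4.9, 2.9, 5, kind="SEM")
        assert sd.sd == pytest.approx(sem.sd)

    def test_zero_variance_equal_means(self):
        res = ttest_two_sample([2.0, 2.0], [2.0, 2.0])
        assert (res.statistic, res.p_value) == (0.0, 1.0)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="n ≥ 2"):
            ttest_two_sample([1.0], [1.0, 2.0])

    def test_nonpositive_dispersion_rejected(self):
        with pytest.raises(ValueError, match="dispersion"):
            ttest_from_summary(GroupSummary(1, 0, 5), GroupSummary(0, 1, 5))


class TestPermutationTest:
    def test_exhaustive_enumeration_hand_case(self):
        res = permutation_test([1.0, 2.0], [3.0, 4.0])
        assert res.p_value == pytest.approx(2 / 6)
        assert res.method == "permutation_exhaustive"

    def test_constant_data_p_one(self):
        res = permutation_test([5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.p_value == 1.0

    def test_montecarlo_close_to_exhaustive(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(1, 1, 6), rng.normal(0, 1, 6)
        exact = permutation_test(a, b).p_value
        mc = permutation_test(a, b, n_perm=4000, seed=3, exhaustive_cap=10).p_value
        assert abs(mc - exact) < 0.05

    def test_small_n_perm_warns(self):
        with pytest.warns(UserWarning, match="small"):
            permutation_test(np.arange(10.0), np.arange(10.0) + 1,
                             n_perm=50, seed=0, exhaustive_cap=10)

    def test_null_p_values_approximately_uniform(self):
        from scipy import stats

        rng = np.random.default_rng(4)
        ps = []
        for seed in range(300):
            a, b = rng.normal(0, 1, 50), rng.normal(0, 1, 50)
            ps.append(permutation_test(a, b, n_perm=199, seed=seed).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestKsTwoSample:
    def test_identical_samples(self):
        res = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_disjoint_supports(self):
        assert ks_two_sample([1, 2, 3], [4, 5, 6]).statistic == pytest.approx(1.0)

    def test_interleaved_hand_case(self):
        assert ks_two_sample([1, 3], [2, 4]).statistic == pytest.approx(0.5)

    def test_exact_mode(self):
        res = ks_two_sample([1, 3], [2, 4], mode="exact")
        assert 0 < res.p_value <= 1


class TestScoreFormulas:
    def test_fcs_hand_values(self):
        up = compute_fcs(GroupSummary(4, 1, 3), GroupSummary(2, 1, 3), 0.01)
        down = compute_fcs(GroupSummary(1, 1, 3), GroupSummary(2, 1, 3), 0.1)
        assert up == pytest.approx(2.0)
        assert down == pytest.approx(-1.0)

    def test_fcs_zero_for_equal_means(self):
        assert compute_fcs(GroupSummary(3, 1, 3), GroupSummary(3, 2, 4), 0.42) == 0.0

    def test_fcs_undefined_for_nonpositive_mean(self):
        assert compute_fcs(GroupSummary(0.0, 1, 3), GroupSummary(2, 1, 3), 0.1) is None
        with_pc = compute_fcs(
            GroupSummary(0.0, 1, 3), GroupSummary(2, 1, 3), 0.1, pseudocount=0.5
        )
        assert with_pc == pytest.approx(math.log2(0.5 / 2.5))

    def test_sns_hand_values(self):
        v = compute_sns(GroupSummary(5, 1, 3), GroupSummary(3, 1, 3), 0.1)
        assert v == pytest.approx(1.0)
        v2 = compute_sns(GroupSummary(0.5, 0.5, 3), GroupSummary(1.5, 0.5, 3), 0.01)
        assert v2 == pytest.approx(-2.0)

    def test_sns_zero_for_equal_means(self):
        assert compute_sns(GroupSummary(2, 1, 3), GroupSummary(2, 3, 5), 0.2) == 0.0

    def test_p_zero_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            compute_sns(GroupSummary(1, 1, 3), GroupSummary(0, 1, 3), 0.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(mu_t=positive, mu_c=positive, sd_t=positive, sd_c=positive,
           p=pvals, scale=st.floats(0.01, 100))
    def test_scores_invariant_under_rescaling(self, mu_t, mu_c, sd_t, sd_c, p, scale):
        a, b = GroupSummary(mu_t, sd_t, 5), GroupSummary(mu_c, sd_c, 5)
        a2 = GroupSummary(mu_t * scale, sd_t * scale, 5)
        b2 = GroupSummary(mu_c * scale, sd_c * scale, 5)
        assert compute_fcs(a, b, p) == pytest.approx(compute_fcs(a2, b2, p), rel=1e-9)
        assert compute_sns(a, b, p) == pytest.approx(compute_sns(a2, b2, p), rel=1e-9)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(mu_t=positive, mu_c=positive, sd_t=positive, sd_c=positive, p=pvals)
    def test_scores_share_sign_of_mean_difference(self, mu_t, mu_c, sd_t, sd_c, p):
        a, b = GroupSummary(mu_t, sd_t, 5), GroupSummary(mu_c, sd_c, 5)
        fcs, sns = compute_fcs(a, b, p), compute_sns(a, b, p)
        expected = np.sign(mu_t - mu_c) if p < 1 else 0.0
        assert np.sign(fcs) == expected
        assert np.sign(sns) == expected


class TestScoreGenes:
    def test_planted_gene_tops_both_rankings(self):
        config = SimulationConfig(
            n_genes=200,
            genes_per_role={"planted_degs": 1, "negative_probes": 5},
            regions={"SN": 15},
            groups=[("GqCNO", 2), ("GqVeh", 2)],
            deg_effects={"Deg0001": 4.0},
            seed=0,
        )
        ds = simulate_visium_dataset(config)
        table = score_genes(ds.matrix, "GqCNO", "GqVeh").table.set_index("gene")
        assert table.loc["Deg0001", "fcs_rank"] == 1
        assert table.loc["Deg0001", "sns_rank"] == 1

    def test_identical_gene_gets_worst_rank(self):
        from tests.conftest import make_matrix

        rng = np.random.default_rng(5)
        counts = rng.poisson(10, size=(12, 4)).astype(float) + 1
        counts[:, 0] = [1, 2, 3, 4, 5, 6] * 2  # identical across groups
        m = make_matrix(counts, group=["t"] * 6 + ["c"] * 6)
        table = score_genes(m, "t", "c").table
        row = table.iloc[0]
        assert row["p_value"] == 1.0
        assert row["fcs"] == 0.0 and row["sns"] == 0.0
        assert row["fcs_rank"] == table["fcs_rank"].max()
        assert row["sns_rank"] == table["sns_rank"].max()

    def test_scale_invariance_of_table(self, default_dataset):
        m = default_dataset.matrix
        mask = np.isin(m.spot_meta["region_truth"], ("SN", "VTA"))
        t1 = score_genes(m, "GqCNO", "GqVeh", region_mask=mask).table
        m3 = m.copy()
        m3.counts = m3.counts * 3
        t3 = score_genes(m3, "GqCNO", "GqVeh", region_mask=mask).table
        np.testing.assert_allclose(t1["p_value"], t3["p_value"], rtol=1e-9)
        np.testing.assert_allclose(t1["fcs"], t3["fcs"], rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(t1["sns"], t3["sns"], rtol=1e-9, atol=1e-12)

    def test_missing_group_named_in_error(self, default_dataset):
        with pytest.raises(ValueError, match="nosuch"):
            score_genes(default_dataset.matrix, "nosuch", "GqVeh")


class TestCallHits:
    def _tables(self, dataset):
        m = dataset.matrix
        mask = np.isin(m.spot_meta["region_truth"], ("SN", "VTA"))
        t1 = score_genes(m, "GqCNO", "GqVeh", region_mask=mask)
        t2 = score_genes(m, "GqCNO", "CNO", region_mask=mask)
        return t1, t2

    def test_gene_significant_in_one_contrast_is_not_a_hit(self, default_dataset):
        t1, t2 = self._tables(default_dataset)
        only_one = (t1.table["p_value"] < 0.05) & (t2.table["p_value"] > 0.2)
        assert only_one.any()
        hits = set(call_hits(t1, t2).genes)
        assert not (set(t1.table.loc[only_one, "gene"]) & hits)

    def test_alpha_one_topk_all_returns_everything(self, default_dataset):
        t1, t2 = self._tables(default_dataset)
        hits = call_hits(t1, t2, alpha=1.0 + 1e-9, top_k="all")
        assert len(hits.genes) == len(t1.table)

    def test_planted_degs_recovered(self, default_dataset):
        t1, t2 = self._tables(default_dataset)
        hits = set(call_hits(t1, t2).genes)
        planted = set(default_dataset.truth["gene"])
        assert len(planted & hits) >= 18
        null_rate = len(hits - planted) / (len(t1.table) - len(planted))
        assert null_rate <= 0.05

    def test_top_k_restricts_to_both_rankings(self, default_dataset):
        t1, t2 = self._tables(default_dataset)
        hits = call_hits(t1, t2, top_k=10)
        tb = t1.table.set_index("gene")
        for g in hits.genes:
            assert tb.loc[g, "fcs_rank"] <= 10 and tb.loc[g, "sns_rank"] <= 10

    def test_null_dual_contrast_rate_bounded(self, null_dataset):
        t1, t2 = self._tables(null_dataset)
        hits = call_hits(t1, t2)
        # the two contrasts share the treated group, so only the marginal
        # alpha bound is asserted; the empirical rate is recorded
        rate = len(hits.genes) / len(t1.table)
        assert rate <= 0.05 + 0.01

    def test_mismatched_universe_errors(self, default_dataset):
        t1, t2 = self._tables(default_dataset)
        t2.table = t2.table.iloc[:-1]
        with pytest.raises(ValueError, match="universe"):
            call_hits(t1, t2)


class TestHolmSidak:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_sidak_adjust([0.03]), [0.03])

    def test_two_p_hand_case(self):
        adj = holm_sidak_adjust([0.01, 0.04])
        assert adj[0] == pytest.approx(1 - 0.99**2)
        assert adj[1] == pytest.approx(0.04)

    def test_ties_hand_case(self):
        np.testing.assert_allclose(
            holm_sidak_adjust([0.05, 0.05, 0.05]), 1 - 0.95**3
        )

    def test_order_preserved(self):
        p = [0.2, 0.01, 0.9, 0.04]
        adj = holm_sidak_adjust(p)
        assert np.argsort(adj).tolist() == np.argsort(p).tolist()

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_adjusted_dominate_raw_and_capped(self, p):
        adj = holm_sidak_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            holm_sidak_adjust([0.5, 1.5])
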