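import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spotrank import (
    evaluate_normalizations,
    ma_correlation,
    normalize_activity_scores,
    normalize_counts,
    pca_on_median_normalized,
    pseudobulk_by_sample,
    simulate_depth_series,
)
from spotrank.normalization import UnavailableMethodError
from tests.conftest import make_matrix


class TestNormalizeCounts:
    def test_quantile_hand_example(self):
        m = make_matrix(np.array([[1, 2, 3], [4, 5, 6]]))
        out = normalize_counts(m, "quantile")
        np.testing.assert_allclose(out.counts, [[2.5, 3.5, 4.5], [2.5, 3.5, 4.5]])

    def test_quantile_identity_on_identical_samples(self):
        m = make_matrix(np.array([[3, 1, 2], [3, 1, 2]]))
        out = normalize_counts(m, "quantile")
        np.testing.assert_allclose(out.counts, m.counts)

    def test_quantile_equalizes_sorted_vectors_exactly(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.lognormal(size=(5, 40)))  # tie-free values
        out = normalize_counts(m, "quantile")
        s = np.sort(out.counts, axis=1)
        assert np.abs(s - s[0]).max() < 1e-9

    def test_quantile_idempotent(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.lognormal(size=(4, 30)))
        once = normalize_counts(m, "quantile")
        twice = normalize_counts(once, "quantile")
        np.testing.assert_allclose(twice.counts, once.counts, atol=1e-12)

    def test_quantile_averages_ties(self):
        # tied values within a row share the average of their rank targets
        m = make_matrix(np.array([[1.0, 1.0, 4.0], [2.0, 6.0, 10.0]]))
        out = normalize_counts(m, "quantile")
        assert out.counts[0, 0] == out.counts[0, 1]

    def test_libsize_hand_example(self):
        # one sample [1,1,2] against another totalling 12: mean total 8
        m = make_matrix(np.array([[1, 1, 2], [3, 4, 5]]))
        out = normalize_counts(m, "libsize")
        np.testing.assert_allclose(out.counts[0], [2, 2, 4])
        np.testing.assert_allclose(out.counts.sum(axis=1), [8, 8])

    def test_q3_postcondition(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.poisson(20, size=(4, 100)))
        raw_q3 = np.percentile(m.counts, 75, axis=1)
        out = normalize_counts(m, "q3")
        np.testing.assert_allclose(
            np.percentile(out.counts, 75, axis=1), raw_q3.mean()
        )

    def test_background_divides_by_neg_probe_mean(self):
        counts = np.array([[2.0, 4.0, 8.0], [1.0, 3.0, 5.0]])
        m = make_matrix(counts, roles=["neg_probe", "other", "other"])
        out = normalize_counts(m, "background")
        np.testing.assert_allclose(out.counts[0], counts[0] / 2.0)
        np.testing.assert_allclose(out.counts[1], counts[1] / 1.0)

    def test_background_requires_neg_probes(self):
        m = make_matrix(np.ones((2, 3)))
        with pytest.raises(ValueError, match="neg_probe"):
            normalize_counts(m, "background")

    def test_median_postcondition(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.poisson(10, size=(3, 50)) + 1)
        out = normalize_counts(m, "median")
        meds = [np.median(r[r > 0]) for r in out.counts]
        np.testing.assert_allclose(meds, meds[0])

    def test_sctransform_is_explicitly_unavailable(self):
        m = make_matrix(np.ones((2, 3)))
        with pytest.raises(UnavailableMethodError, match="sctransform"):
            normalize_counts(m, "sctransform")

    @pytest.mark.parametrize("method", ["quantile", "q3", "background", "libsize",
                                        "median"])
    def test_shape_and_order_preserved(self, method):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.poisson(10, size=(4, 30)) + 1,
                        roles=["neg_probe"] * 3 + ["other"] * 27)
        out = normalize_counts(m, method)
        assert out.counts.shape == m.counts.shape
        assert out.gene_meta.equals(m.gene_meta)


class TestMaCorrelation:
    def test_identical_samples_give_zero(self):
        a = np.array([1.0, 5.0, 9.0])
        assert ma_correlation(a, a) == 0.0

    def test_hand_pearson_three_points(self):
        # M = 2A − 2 exactly → |r| = 1
        assert ma_correlation([1, 2, 8], [2, 2, 2], pseudocount=0) == pytest.approx(1.0)

    def test_proportional_samples_give_zero(self):
        a = np.array([1.0, 2.0, 8.0])
        assert ma_correlation(a, 3.0 * a, pseudocount=0) == 0.0

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(5)
        a, b = rng.lognormal(size=30), rng.lognormal(size=30)
        assert ma_correlation(a, b) == pytest.approx(ma_correlation(b, a))

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            ma_correlation([1, 2, 3], [1, 2])


class TestEvaluateNormalizations:
    def test_identical_samples_score_zero_everywhere(self):
        row = np.arange(1.0, 31.0)
        m = make_matrix(np.tile(row, (3, 1)),
                        roles=["neg_probe"] * 2 + ["other"] * 28)
        report = evaluate_normalizations(m)
        avail = report.scores[report.scores["available"]]
        assert (avail["ma_score"] == 0).all()
        assert (avail["ks_significant_fraction"] == 0).all()

    def test_quantile_wins_on_depth_differences(self):
        m = simulate_depth_series(seed=0)
        report = evaluate_normalizations(m)
        assert report.chosen_method == "quantile"
        q = report.scores.set_index("method")
        assert q.loc["quantile", "ks_significant_fraction"] == 0.0

    def test_raw_depth_differences_are_ks_significant(self):
        from scipy import stats

        m = simulate_depth_series(seed=0)
        flags = [
            stats.ks_2samp(m.counts[i], m.counts[j]).pvalue < 0.05
            for i in range(m.n_spots)
            for j in range(i + 1, m.n_spots)
        ]
        assert np.mean(flags) > 0.0

    def test_quantile_reevaluation_is_stable(self):
        m = simulate_depth_series(seed=0)
        q = normalize_counts(m, "quantile")
        report = evaluate_normalizations(q, methods=["quantile"])
        row = report.scores.iloc[0]
        assert row["ks_significant_fraction"] == 0.0
        # re-evaluating the already-normalized matrix reproduces the scores
        again = evaluate_normalizations(q, methods=["quantile"]).scores.iloc[0]
        assert again["ma_score"] == row["ma_score"]
        assert again["ks_significant_fraction"] == 0.0

    def test_sctransform_recorded_unavailable(self):
        m = simulate_depth_series(n_samples=3, n_genes=100, seed=1)
        report = evaluate_normalizations(m)
        row = report.scores.set_index("method").loc["sctransform"]
        assert not row["available"]
        assert np.isnan(row["ma_score"])

    def test_ranking_invariant_to_sample_order(self):
        m = simulate_depth_series(n_samples=4, n_genes=300, seed=2)
        report = evaluate_normalizations(m)
        perm = m.subset_spots(np.array([2, 0, 3, 1]))
        report_perm = evaluate_normalizations(perm)
        assert report.chosen_method == report_perm.chosen_method

    def test_single_sample_errors(self):
        m = make_matrix(np.ones((1, 5)))
        with pytest.raises(ValueError, match="≥ 2 samples"):
            evaluate_normalizations(m)


class TestPcaOnMedianNormalized:
    def test_planted_group_shift_separates_on_pc1(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(0)
        base = rng.lognormal(2, 0.3, size=(30, 50))
        shift = np.repeat([0.0, 4.0, 8.0], 10)
        base[:, :10] *= (1 + shift)[:, None]
        labels = np.repeat(["a", "b", "c"], 10)
        m = make_matrix(base)
        emb = pca_on_median_normalized(m, labels)
        score = silhouette_score(emb.scores[:, :1], labels)
        assert score > 0.5

    def test_two_observations_give_one_component(self):
        m = make_matrix(np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]))
        emb = pca_on_median_normalized(m, ["a", "b"])
        assert emb.scores.shape[1] == 1
        assert emb.explained_variance[0] == pytest.approx(1.0)

    def test_identical_observations_warn_and_zero(self):
        m = make_matrix(np.tile([1.0, 2.0, 3.0], (4, 1)))
        with pytest.warns(UserWarning, match="identical"):
            emb = pca_on_median_normalized(m, ["a", "a", "b", "b"])
        assert np.all(emb.scores == 0)
        assert np.all(emb.explained_variance == 0)

    def test_gene_filter_requires_expression_in_all_groups(self):
        counts = np.array([[1.0, 0.0, 5.0], [2.0, 0.0, 1.0],
                           [3.0, 4.0, 2.0], [1.0, 5.0, 3.0]])
        m = make_matrix(counts)
        emb = pca_on_median_normalized(m, ["a", "a", "b", "b"])
        # gene 1 absent in group a → filtered
        assert list(emb.genes) == ["Gene0", "Gene2"]

    def test_explained_variance_nonincreasing(self):
        rng = np.random.default_rng(6)
        m = make_matrix(rng.lognormal(size=(12, 20)))
        emb = pca_on_median_normalized(m, ["g"] * 12)
        assert np.all(np.diff(emb.explained_variance) <= 1e-12)
        assert emb.explained_variance.sum() <= 1 + 1e-9


class TestNormalizeActivityScores:
    def test_single_section_hand_example(self):
        out = normalize_activity_scores([1, 2, 3], ["s1", "s1", "s1"])
        np.testing.assert_allclose(out, [0.5, 1.0, 1.5])

    def test_constant_scores_become_one(self):
        out = normalize_activity_scores([7, 7, 7, 7], ["a", "a", "b", "b"])
        np.testing.assert_allclose(out, 1.0)

    def test_scale_cancels_between_sections(self):
        base = np.array([1.0, 2.0, 5.0])
        scores = np.concatenate([3 * base, 11 * base])
        sections = ["a"] * 3 + ["b"] * 3
        out = normalize_activity_scores(scores, sections)
        np.testing.assert_allclose(out[:3], out[3:])

    def test_every_section_mean_is_one(self):
        rng = np.random.default_rng(7)
        scores = rng.lognormal(size=20)
        sections = np.repeat(["a", "b", "c", "d"], 5)
        out = normalize_activity_scores(scores, sections)
        for s in "abcd":
            assert out[sections == s].mean() == pytest.approx(1.0)

    def test_zero_section_mean_errors(self):
        with pytest.raises(ValueError, match="zero mean"):
            normalize_activity_scores([0.0, 0.0], ["a", "a"])


def test_pseudobulk_sums_spots(default_dataset):
    m = default_dataset.matrix
    pb = pseudobulk_by_sample(m)
    assert pb.n_spots == m.spot_meta["sample"].nunique()
    first = sorted(m.spot_meta["sample"].unique())[0]
    np.testing.assert_array_equal(
        pb.counts[0], m.counts[m.spot_meta["sample"] == first].sum(axis=0)
    )
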