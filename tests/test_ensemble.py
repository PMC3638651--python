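"""Random-subset averaging, rerank aggregation, prescreen and the pipeline."""

import itertools
import math

import numpy as np
import pytest

from rerankfs import (
    InvalidInputError,
    RerankConfig,
    SimDesign,
    feature_matrix,
    full_pipeline,
    gaussian_two_group,
    prescreen,
    random_subset_scores,
    rank_scores,
    rerank,
)
from rerankfs.ensemble import retain_count, subset_size


def exhaustive_subset_average(data, k):
    """Independent oracle for S*: the exact average of S_j over all size-k
    subsets containing j, by full enumeration."""
    p = data.p
    total = np.zeros(p)
    count = np.zeros(p)
    for cols in itertools.combinations(range(p), k):
        cols = np.array(cols)
        s = rank_scores(data.select_markers(cols)).s
        total[cols] += s
        count[cols] += 1
    return total / count


class TestRandomSubsetScores:
    def test_null_data_gives_zero(self, null_matrix):
        res = random_subset_scores(null_matrix, B=25, seed=0)
        np.testing.assert_array_equal(res.s_star, np.zeros(null_matrix.p))

    @pytest.mark.parametrize("engine", ["fast", "reference"])
    def test_matches_exhaustive_enumeration(self, engine):
        """Monte-Carlo S* converges to the exact all-subsets average (p=4, k=2)."""
        rng = np.random.default_rng(12)
        data = feature_matrix(rng.standard_normal((10, 4)), [1] * 5 + [0] * 5)
        exact = exhaustive_subset_average(data, 2)
        B = 2000
        res = random_subset_scores(data, B=B, seed=99, engine=engine)
        # per-subset scores are bounded by k-1=1; a conservative SE bound
        se = 1.0 / np.sqrt(res.inclusion_counts)
        assert np.all(np.abs(res.s_star - exact[res.active]) <= 3 * se)

    def test_p2_subset_is_everything(self, tiny_pair):
        res = random_subset_scores(tiny_pair, B=7, seed=1)
        np.testing.assert_array_equal(res.s_star, rank_scores(tiny_pair).s)
        np.testing.assert_array_equal(res.inclusion_counts, [7, 7])

    def test_every_marker_covered(self):
        rng = np.random.default_rng(5)
        data = feature_matrix(rng.standard_normal((6, 30)), [1] * 3 + [0] * 3)
        res = random_subset_scores(data, B=1, seed=3)  # B=1 leaves half uncovered
        assert res.inclusion_counts.min() >= 1

    def test_too_few_markers_rejected(self, tiny_pair):
        with pytest.raises(InvalidInputError):
            random_subset_scores(tiny_pair, active=np.array([0]), B=5)

    def test_engines_agree(self, small_signal):
        data, _ = small_signal
        a = random_subset_scores(data, B=40, seed=8, engine="fast")
        b = random_subset_scores(data, B=40, seed=8, engine="reference")
        np.testing.assert_allclose(a.s_star, b.s_star, atol=1e-10)

    def test_engines_agree_on_ties(self):
        vals = np.round(np.random.default_rng(2).standard_normal((8, 20)), 1)
        data = feature_matrix(vals, [1] * 4 + [0] * 4)
        a = random_subset_scores(data, B=40, seed=8, engine="fast")
        b = random_subset_scores(data, B=40, seed=8, engine="reference")
        np.testing.assert_allclose(a.s_star, b.s_star, atol=1e-10)


class TestSizingRules:
    @pytest.mark.parametrize("pa, k", [(2, 2), (3, 2), (4, 2), (5, 3), (101, 51)])
    def test_subset_size_half_rule(self, pa, k):
        assert subset_size(pa) == k

    def test_retention_is_top_q_percent(self):
        # q = 87.5 of 2000 markers keeps ceil(1750) = 1750
        assert retain_count(2000, 87.5) == 1750

    def test_retention_strictly_decreases(self):
        for p_t in range(2, 50):
            assert retain_count(p_t, 99.9) <= p_t - 1


class TestRerank:
    def test_null_data_all_zero(self, null_matrix):
        res = rerank(null_matrix, B=20, stop_floor=2, seed=0)
        np.testing.assert_array_equal(res.s_star_star, np.zeros(null_matrix.p))
        assert all(rec.w_t == 0.0 for rec in res.iterations)

    def test_active_sets_nested_and_shrinking(self, small_signal):
        data, _ = small_signal
        res = rerank(data, B=30, stop_floor=3, seed=2)
        sizes = [rec.p_t for rec in res.iterations]
        assert sizes == sorted(sizes, reverse=True)
        assert all(a > b for a, b in zip(sizes, sizes[1:]))
        for prev, nxt in zip(res.iterations, res.iterations[1:]):
            assert set(nxt.active) < set(prev.active)
        # last scored set is still at least the stop floor
        assert sizes[-1] >= 3
        assert res.T == len(res.iterations) - 1

    def test_deterministic_given_seed(self, small_signal):
        data, _ = small_signal
        a = rerank(data, B=30, stop_floor=3, seed=11)
        b = rerank(data, B=30, stop_floor=3, seed=11)
        assert np.array_equal(a.s_star_star, b.s_star_star)
        assert np.array_equal(a.dropped_at, b.dropped_at)

    def test_strong_markers_win(self, small_signal):
        data, truth = small_signal
        res = rerank(data, B=50, stop_floor=3, seed=4)
        top3 = np.argsort(-res.s_star_star)[:3]
        assert set(top3) == set(truth.relevant)

    def test_dominant_marker_survives_to_final_iteration(self):
        design = SimDesign(p=40, m_star=1, delta=4.0, n1=10, n0=10, seed=31)
        data, truth = gaussian_two_group(design)
        res = rerank(data, B=50, stop_floor=3, seed=4)
        assert np.argmax(res.s_star_star) == truth.relevant[0]
        assert truth.relevant[0] in res.iterations[-1].active

    def test_dropped_markers_keep_only_their_iterations(self, small_signal):
        """A marker dropped at iteration t accumulates exactly t+1 terms of
        the weighted sum; recomputing the sum from the records must agree."""
        data, _ = small_signal
        res = rerank(data, B=30, stop_floor=3, seed=9)
        rebuilt = np.zeros(data.p)
        for rec in res.iterations:
            rebuilt[rec.active] += rec.w_t * rec.s_star / rec.p_t
        np.testing.assert_allclose(rebuilt, res.s_star_star, atol=1e-14)
        for j in range(data.p):
            t_drop = res.dropped_at[j]
            if t_drop >= 0:
                assert all(
                    (j in rec.active) == (t < t_drop)
                    for t, rec in enumerate(res.iterations)
                )

    def test_column_order_invariance(self, small_signal):
        """Permuting input columns permutes the scores identically (same ids)."""
        data, _ = small_signal
        perm = np.random.default_rng(0).permutation(data.p)
        shuffled = feature_matrix(
            data.values[:, perm], data.labels, data.marker_ids[perm]
        )
        a = rerank(data, B=30, stop_floor=3, seed=5)
        b = rerank(shuffled, B=30, stop_floor=3, seed=5)
        np.testing.assert_array_equal(a.s_star_star[perm], b.s_star_star)

    def test_invalid_q_rejected(self, small_signal):
        data, _ = small_signal
        with pytest.raises(InvalidInputError):
            rerank(data, q=100.0, seed=0)


class TestPrescreen:
    def test_keeps_all_when_m0_large(self, small_signal):
        data, _ = small_signal
        np.testing.assert_array_equal(prescreen(data, 1000), np.arange(data.p))

    def test_top_by_absolute_t(self):
        rng = np.random.default_rng(6)
        vals = rng.standard_normal((20, 3))
        vals[:10, 0] += 5.0   # |t| huge
        vals[:10, 2] += 3.0   # |t| large
        data = feature_matrix(vals, [1] * 10 + [0] * 10)
        np.testing.assert_array_equal(prescreen(data, 2), [0, 2])

    def test_monotone_in_m0(self, small_signal):
        data, _ = small_signal
        kept = [set(prescreen(data, m0)) for m0 in (5, 10, 20, 40)]
        for smaller, larger in zip(kept, kept[1:]):
            assert smaller <= larger


class TestFullPipeline:
    def test_relevant_markers_lead_the_list(self, small_signal):
        data, truth = small_signal
        cfg = RerankConfig(M0=None, B=50, stop_floor=3, seed=1)
        result = full_pipeline(data, cfg)
        assert set(result.order[:3]) == set(truth.relevant)
        assert list(result.table["rank"]) == list(range(1, data.p + 1))

    def test_single_relevant_marker_ranked_first(self):
        design = SimDesign(p=30, m_star=1, delta=4.0, n1=12, n0=12, seed=21)
        data, truth = gaussian_two_group(design)
        cfg = RerankConfig(M0=None, B=50, stop_floor=2, seed=2)
        result = full_pipeline(data, cfg)
        assert result.order[0] == truth.relevant[0]

    def test_prescreened_markers_appended_by_t(self, small_signal):
        data, _ = small_signal
        cfg = RerankConfig(M0=10, B=30, stop_floor=3, seed=3)
        result = full_pipeline(data, cfg)
        assert len(result.screened) == 10
        tail = result.table.iloc[10:]
        assert not tail["screened"].any()
        assert (tail["dropped_at"] == -2).all()
        t_tail = tail["t_score"].to_numpy()
        assert np.all(np.diff(t_tail) <= 1e-12)  # sorted by |t| descending

    def test_null_data_orders_by_t(self, null_matrix):
        cfg = RerankConfig(M0=None, B=20, stop_floor=2, seed=0)
        result = full_pipeline(null_matrix, cfg)
        assert (result.table["s_star_star"] == 0).all()
        t_sorted = result.table["t_score"].to_numpy()
        assert np.all(np.diff(t_sorted) <= 1e-12)
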