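import numpy as np
import pytest

from conftest import block_similarity_matrix, brute_force_rand, random_partition
from natscales.graph import PercentileThresholds
from natscales.scales import (
    NaturalScale,
    ScaleSpace,
    detect_breakpoints,
    interval_separation,
    intervals_from_breakpoints,
    natural_scales,
    normalized_dissimilarity,
    pair_agreement,
    prototypical_scale,
    rand_similarity,
    similarity_matrix,
    user_scale_contributions,
)


def scalespace_from_matrix(mat):
    """ScaleSpace carrying only a similarity matrix (partitions unused)."""
    n = len(mat)
    return ScaleSpace({s: {} for s in range(1, n + 1)}, np.asarray(mat, dtype=float))


class TestPairAgreement:
    def test_indicator_values(self):
        p = {"a": 0, "b": 0, "c": 1}
        assert pair_agreement(p, "a", "b") == 1
        assert pair_agreement(p, "a", "c") == 0

    def test_symmetric(self, rng):
        p = random_partition(rng, [f"x{i}" for i in range(10)], 3)
        for i in p:
            for j in p:
                assert pair_agreement(p, i, j) == pair_agreement(p, j, i)

    def test_unknown_location(self):
        with pytest.raises(ValueError):
            pair_agreement({"a": 0}, "a", "zz")


class TestRandSimilarity:
    def test_worked_three_element_example(self):
        # P = {{a,b},{c}} vs P' = {{a},{b},{c}}: of the 3 pairs only (a,b)
        # is classified differently -> delta = 2/3
        p = {"a": 0, "b": 0, "c": 1}
        q = {"a": 0, "b": 1, "c": 2}
        assert rand_similarity(p, q) == pytest.approx(2 / 3)
        assert rand_similarity(p, q) == brute_force_rand(p, q)

    def test_self_similarity_is_one(self, rng):
        p = random_partition(rng, [f"x{i}" for i in range(20)], 4)
        assert rand_similarity(p, p) == 1.0

    def test_matches_brute_force_on_random_pairs(self, rng):
        domain = [f"x{i}" for i in range(50)]
        for _ in range(25):
            p = random_partition(rng, domain, int(rng.integers(2, 8)))
            q = random_partition(rng, domain, int(rng.integers(2, 8)))
            assert rand_similarity(p, q) == brute_force_rand(p, q)

    def test_label_permutation_invariant(self, rng):
        domain = [f"x{i}" for i in range(30)]
        p = random_partition(rng, domain, 4)
        q = random_partition(rng, domain, 4)
        q2 = {k: (v * 7 + 3) % 13 for k, v in q.items()}
        assert rand_similarity(p, q) == rand_similarity(p, q2)

    def test_symmetry(self, rng):
        domain = [f"x{i}" for i in range(30)]
        p = random_partition(rng, domain, 4)
        q = random_partition(rng, domain, 5)
        assert rand_similarity(p, q) == rand_similarity(q, p)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import rand_score

        domain = [f"x{i}" for i in range(40)]
        for _ in range(10):
            p = random_partition(rng, domain, 5)
            q = random_partition(rng, domain, 5)
            expected = rand_score([p[d] for d in domain], [q[d] for d in domain])
            assert rand_similarity(p, q) == pytest.approx(expected, abs=1e-12)

    def test_domain_mismatch_and_tiny_domain(self):
        with pytest.raises(ValueError, match="domain"):
            rand_similarity({"a": 0}, {"b": 0})
        with pytest.raises(ValueError, match="at least 2"):
            rand_similarity({"a": 0}, {"a": 1})


class TestSimilarityMatrix:
    def test_identical_partitions_all_ones(self):
        p = {"a": 0, "b": 0, "c": 1}
        ss = similarity_matrix([p, p, p])
        assert np.array_equal(ss.similarity, np.ones((3, 3)))

    def test_alternating_checkerboard(self):
        p = {"a": 0, "b": 0, "c": 1}
        q = {"a": 0, "b": 1, "c": 2}
        d = rand_similarity(p, q)
        ss = similarity_matrix([p, q, p, q])
        for i in range(4):
            for j in range(4):
                expected = 1.0 if (i % 2) == (j % 2) else d
                assert ss.similarity[i, j] == expected

    def test_symmetry_and_unit_diagonal(self, rng):
        domain = [f"x{i}" for i in range(15)]
        parts = [random_partition(rng, domain, 3) for _ in range(6)]
        ss = similarity_matrix(parts)
        assert np.array_equal(ss.similarity, ss.similarity.T)
        assert np.array_equal(np.diag(ss.similarity), np.ones(6))
        assert ss.similarity.min() >= 0 and ss.similarity.max() <= 1


class TestNormalizedDissimilarity:
    def test_anchors_and_monotonicity(self):
        mat = np.array([[1.0, 0.6, 0.4], [0.6, 1.0, 0.8], [0.4, 0.8, 1.0]])
        ss = scalespace_from_matrix(mat)
        norm = normalized_dissimilarity(ss)
        assert norm[0, 2] == 1.0  # min similarity 0.4 -> max dissimilarity
        assert np.all(np.diag(norm) == 0.0)
        # monotone transform preserves ordering of entries
        iu = np.triu_indices(3, k=1)
        assert np.array_equal(
            np.argsort((1 - mat)[iu]), np.argsort(norm[iu])
        )

    def test_degenerate_identical_partitions(self):
        ss = scalespace_from_matrix(np.ones((4, 4)))
        with pytest.warns(UserWarning, match="degenerate"):
            norm = normalized_dissimilarity(ss)
        assert np.array_equal(norm, np.zeros((4, 4)))


class TestIntervalSeparation:
    def test_planted_two_block_ratio(self):
        mat = block_similarity_matrix([(1, 10), (11, 20)])
        ss = scalespace_from_matrix(mat)
        assert interval_separation(ss, [11]) == pytest.approx(9.0, rel=1e-12)

    def test_breakpoint_inside_block_scores_lower(self):
        mat = block_similarity_matrix([(1, 10), (11, 20)])
        ss = scalespace_from_matrix(mat)
        best = interval_separation(ss, [11])
        for b in range(2, 21):
            if b != 11:
                assert interval_separation(ss, [b]) < best

    def test_identical_partitions_sigma_one(self):
        ss = scalespace_from_matrix(np.ones((20, 20)))
        for b in (5, 11, 17):
            assert interval_separation(ss, [b]) == 1.0

    def test_empty_breakpoints_undefined(self):
        ss = scalespace_from_matrix(np.ones((10, 10)))
        with pytest.raises(ValueError, match="undefined"):
            interval_separation(ss, [])

    def test_zero_denominator_gives_infinity(self):
        mat = block_similarity_matrix([(1, 5), (6, 10)], within=1.0, across=0.0)
        ss = scalespace_from_matrix(mat)
        assert interval_separation(ss, [6]) == np.inf

    def test_singleton_interval_contributes_unit_similarity(self):
        mat = block_similarity_matrix([(1, 9), (10, 10)], within=0.8, across=0.2)
        ss = scalespace_from_matrix(mat)
        # numerator = (9*0.8 + 1*1.0)/10, denominator = delta(9,10) = 0.2
        assert interval_separation(ss, [10]) == pytest.approx((9 * 0.8 + 1.0) / 10 / 0.2)


class TestIntervals:
    def test_partition_of_percentiles(self):
        assert intervals_from_breakpoints([11], 20) == [(1, 10), (11, 20)]
        assert intervals_from_breakpoints([31, 61], 100) == [(1, 30), (31, 60), (61, 100)]

    def test_invalid_positions(self):
        with pytest.raises(ValueError):
            intervals_from_breakpoints([1], 20)
        with pytest.raises(ValueError):
            intervals_from_breakpoints([25], 20)


class TestDetectBreakpoints:
    def test_recovers_two_block_boundary(self):
        mat = block_similarity_matrix([(1, 40), (41, 100)])
        ss = scalespace_from_matrix(mat)
        assert detect_breakpoints(ss) == [41]

    def test_recovers_three_block_boundaries(self):
        mat = block_similarity_matrix([(1, 30), (31, 60), (61, 100)])
        ss = scalespace_from_matrix(mat)
        assert detect_breakpoints(ss) == [31, 61]

    def test_greedy_matches_exhaustive_two_breakpoint_search(self):
        mat = block_similarity_matrix([(1, 30), (31, 60), (61, 100)])
        ss = scalespace_from_matrix(mat)
        best = None
        for b1 in range(6, 97):
            for b2 in range(b1 + 5, 97):
                if b1 - 1 >= 5 and b2 - b1 >= 5 and 101 - b2 >= 5:
                    sig = interval_separation(ss, [b1, b2])
                    if best is None or sig > best[0]:
                        best = (sig, [b1, b2])
        assert detect_breakpoints(ss) == best[1]

    def test_min_interval_guard_never_isolates_terminal_noise(self):
        # a 3-percentile noisy tail cannot become its own interval
        mat = block_similarity_matrix([(1, 97), (98, 100)], within=0.95, across=0.05)
        bps = detect_breakpoints(scalespace_from_matrix(mat), min_interval_size=5)
        for lo, hi in intervals_from_breakpoints(bps, 100):
            assert hi - lo + 1 >= 5
        assert 98 not in bps

    def test_needs_enough_percentiles(self):
        ss = scalespace_from_matrix(np.ones((8, 8)))
        with pytest.raises(ValueError):
            detect_breakpoints(ss, min_interval_size=5)


class TestPrototypicalScale:
    def test_strictly_dominant_row_sum(self):
        mat = np.array(
            [
                [1.0, 0.9, 0.8],
                [0.9, 1.0, 0.9],
                [0.8, 0.9, 1.0],
            ]
        )
        # middle scale is most similar to both others
        assert prototypical_scale(scalespace_from_matrix(mat), (1, 3)) == 2

    def test_singleton_interval(self):
        ss = scalespace_from_matrix(np.ones((5, 5)))
        assert prototypical_scale(ss, (4, 4)) == 4

    def test_tie_breaks_to_smallest(self):
        ss = scalespace_from_matrix(np.ones((6, 6)))
        assert prototypical_scale(ss, (2, 5)) == 2


class TestNaturalScales:
    def test_distance_ranges_halfopen_cover(self):
        mat = block_similarity_matrix([(1, 40), (41, 100)])
        ss = scalespace_from_matrix(mat)
        th = PercentileThresholds(tuple(float(s) for s in range(1, 101)))
        nat = natural_scales(ss, th)
        assert len(nat) == 2
        assert nat[0].interval == (1, 40) and nat[1].interval == (41, 100)
        assert nat[0].distance_range_km == (0.0, 40.0)
        assert nat[1].distance_range_km == (40.0, 100.0)
        assert nat[0].interval[0] <= nat[0].prototypical_percentile <= nat[0].interval[1]


class TestUserContributions:
    @pytest.fixture
    def scales(self):
        return [
            NaturalScale((1, 40), 20, (0.0, 40.0)),
            NaturalScale((41, 100), 70, (40.0, 400.0)),
        ]

    @pytest.fixture
    def locations(self):
        from natscales.io import Location

        # along the equator: 1 deg lon ~ 111.2 km
        return {
            "A": Location("A", 0.0, 0.0),
            "B": Location("B", 0.0, 0.1),  # ~11 km from A
            "C": Location("C", 0.0, 2.0),  # ~222 km from A
        }

    def test_short_mover_contributes_to_first_scale_only(self, scales, locations):
        df = user_scale_contributions({"u": {"A", "B"}}, locations, scales)
        assert df.loc[0, "scales"] == "1"

    def test_straddling_user_contributes_to_both(self, scales, locations):
        df = user_scale_contributions({"u": {"A", "B", "C"}}, locations, scales)
        assert df.loc[0, "scales"] == "12"
        assert df.loc[0, "activity"] == 3

    def test_single_location_user_contributes_nowhere(self, scales, locations):
        df = user_scale_contributions({"u": {"A"}}, locations, scales)
        assert df.loc[0, "scales"] == ""
        assert df.loc[0, "n_scales"] == 0
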