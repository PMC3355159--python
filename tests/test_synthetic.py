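"""Seeded generators and the benchmark drivers built on them."""

import itertools

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from canberrank import (
    CapabilityError,
    InputError,
    canberra_rank_distance,
    expected_canberra,
    max_distant_ordering,
    measure_closed,
    partial_pair_table,
    random_complete_lists,
    random_partial_lists,
    stability_replicates,
)


class TestRandomCompleteLists:
    def test_each_list_is_a_permutation(self):
        list_set = random_complete_lists(4, 17, seed=0)
        for lst in list_set.lists:
            assert sorted(lst.items) == sorted(list_set.universe.features)

    def test_seed_reproducibility(self):
        assert random_complete_lists(3, 9, seed=5) == random_complete_lists(
            3, 9, seed=5
        )
        assert random_complete_lists(3, 9, seed=5) != random_complete_lists(
            3, 9, seed=6
        )

    def test_rank_one_frequencies_uniform(self):
        # over many draws each of the 5 features heads the list ~1/5 of
        # the time, within 3 binomial standard errors
        n, p = 10_000, 5
        list_set = random_complete_lists(n, p, seed=31)
        heads = [lst.items[0] for lst in list_set.lists]
        se = np.sqrt((1 / p) * (1 - 1 / p) / n)
        for f in list_set.universe.features:
            assert abs(heads.count(f) / n - 1 / p) < 3 * se

    def test_invalid_sizes_rejected(self):
        with pytest.raises(InputError):
            random_complete_lists(1, 5, seed=0)


class TestRandomPartialLists:
    def test_lengths_and_distinctness(self):
        list_set = random_partial_lists(6, 40, 7, seed=1)
        for lst in list_set.lists:
            assert lst.length == 7
            assert len(set(lst.items)) == 7

    def test_shared_support_means_same_feature_set(self):
        list_set = random_partial_lists(6, 40, 7, seed=1, shared_support=True)
        supports = {frozenset(lst.items) for lst in list_set.lists}
        assert len(supports) == 1

    def test_independent_supports_differ(self):
        list_set = random_partial_lists(6, 200, 7, seed=1, shared_support=False)
        supports = {frozenset(lst.items) for lst in list_set.lists}
        assert len(supports) > 1

    def test_shared_support_core_mean_matches_group_mean_ratio(self):
        # core between two orderings of the same support of size l is the
        # plain rank distance on S_l; its expectation over random pairs is
        # E(l), so the normalized mean is E(l)/E(p)
        l, p, n_pairs = 10, 100, 300
        target = expected_canberra(l) / expected_canberra(p)
        values = []
        for k in range(n_pairs):
            pair = random_partial_lists(2, p, l, seed=1000 + k, shared_support=True)
            values.append(
                measure_closed(
                    pair.lists[0], pair.lists[1], pair.universe
                ).core_normalized
            )
        values = np.asarray(values)
        se = values.std(ddof=1) / np.sqrt(n_pairs)
        assert abs(values.mean() - target) < 3 * se

    def test_length_cannot_exceed_universe(self):
        with pytest.raises(InputError):
            random_partial_lists(2, 5, 6, seed=0)


class TestMaxDistantOrdering:
    def test_swap_is_maximal_for_two(self):
        assert max_distant_ordering(2) == (2, 1)
        assert canberra_rank_distance((2, 1), (1, 2)) == pytest.approx(2 / 3)

    @pytest.mark.parametrize("l", [3, 4, 5, 6])
    def test_matches_exhaustive_enumeration(self, l):
        identity = np.arange(1, l + 1)
        best = max(
            canberra_rank_distance(sigma, identity)
            for sigma in itertools.permutations(identity)
        )
        sigma = np.asarray(max_distant_ordering(l), dtype=float)
        assert canberra_rank_distance(sigma, identity) == pytest.approx(
            best, rel=1e-12
        )

    def test_matches_assignment_problem_optimum(self):
        # maximising a sum of per-position costs over permutations is a
        # linear assignment problem: an independent exact oracle
        for l in (5, 8, 10):
            i = np.arange(1, l + 1)[:, None]
            j = np.arange(1, l + 1)[None, :]
            cost = np.abs(i - j) / (i + j)
            rows, cols = linear_sum_assignment(-cost)
            sigma = np.asarray(max_distant_ordering(l), dtype=float)
            assert canberra_rank_distance(sigma, np.arange(1, l + 1)) == pytest.approx(
                float(cost[rows, cols].sum()), rel=1e-12
            )

    def test_refuses_beyond_search_bound(self):
        with pytest.raises(CapabilityError):
            max_distant_ordering(11)


class TestBenchmarkDrivers:
    def test_stability_replicates_shape_and_variance(self):
        mean, variance = stability_replicates(5, 20, replicates=5, seed=0)
        assert variance >= 0.0
        assert 0.5 < mean < 1.5
        with pytest.raises(InputError):
            stability_replicates(5, 20, replicates=1, seed=0)

    def test_partial_pair_table_rows(self):
        rows = partial_pair_table(100, 10, seed=0)
        assert rows["identical"]["core"] == 0.0
        assert rows["identical"]["complete"] > 0.0
        # the unselected-feature term is support-only: additivity is exact
        assert rows["max_distant"]["complete"] == pytest.approx(
            rows["identical"]["complete"] + rows["max_distant"]["core"], rel=1e-12
        )
        assert 0.0 < rows["random"]["core"] <= rows["max_distant"]["core"]

    def test_core_to_complete_ratio_grows_with_relative_length(self):
        # for small l/p the Core and Complete measures are nearly
        # proportional; the mean ratio rises monotonically with l/p
        p = 1000
        ratios = []
        for l in (10, 50, 140):
            vals = []
            for k in range(20):
                pair = random_partial_lists(
                    2, p, l, seed=500 + 31 * l + k, shared_support=True
                )
                bd = measure_closed(pair.lists[0], pair.lists[1], pair.universe)
                vals.append(bd.core / bd.complete)
            ratios.append(np.mean(vals))
        assert ratios[0] < ratios[1] < ratios[2]
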