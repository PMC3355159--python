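"""Complete/Core measures: the three evaluation strategies and their
structural identities."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from canberrank import (
    CapabilityError,
    FeatureUniverse,
    InputError,
    RankedList,
    canberra_rank_distance,
    dualize,
    expected_canberra,
    harmonic_numbers,
    measure_bruteforce,
    measure_closed,
    measure_marginal,
    normalize,
)
from conftest import random_instance, take

STRATEGIES = [measure_marginal, measure_closed]


@pytest.mark.parametrize("measure", STRATEGIES)
class TestStructuralIdentities:
    def test_identical_partial_lists(self, universe100, measure):
        lst = take(universe100, range(10))
        bd = measure(lst, lst, universe100)
        assert bd.t1 == 0.0 and bd.t2 == 0.0
        assert bd.core == 0.0
        assert bd.complete == bd.t3 > 0.0

    def test_complete_lists_reduce_to_rank_distance(self, universe6, measure):
        first = take(universe6, [0, 1, 2, 3, 4, 5])
        second = take(universe6, [5, 3, 1, 0, 2, 4])
        bd = measure(first, second, universe6)
        assert bd.t2 == 0.0 and bd.t3 == 0.0
        d1 = dualize(first, universe6)
        d2 = dualize(second, universe6)
        order = universe6.features
        expected = canberra_rank_distance(
            [d1[f] for f in order], [d2[f] for f in order]
        )
        assert bd.complete == pytest.approx(expected, rel=1e-12)

    def test_identical_complete_lists_have_zero_distance(self, universe6, measure):
        lst = take(universe6, range(6))
        assert measure(lst, lst, universe6).complete == 0.0

    def test_symmetry(self, measure):
        rng = np.random.default_rng(5)
        for _ in range(20):
            first, second, universe = random_instance(rng, 10**4)
            fwd = measure(first, second, universe)
            rev = measure(second, first, universe)
            for field in ("t1", "t2", "t3"):
                assert getattr(fwd, field) == pytest.approx(
                    getattr(rev, field), rel=1e-12, abs=1e-15
                )

    def test_empty_lists_complete_equals_group_mean(self, measure):
        # u = p and the bottom rectangle is the whole square: the measure
        # of two empty lists is exactly E(p)
        universe = FeatureUniverse.auto(9)
        empty = RankedList(())
        bd = measure(empty, empty, universe)
        assert bd.core == 0.0
        assert bd.complete == pytest.approx(expected_canberra(9), rel=1e-12)
        assert bd.complete_normalized == pytest.approx(1.0, rel=1e-12)


class TestStrategyEquivalence:
    def test_reference_shape(self, universe6):
        first = take(universe6, [0, 2, 1])
        second = take(universe6, [3, 0, 5, 4])
        brute = measure_bruteforce(first, second, universe6)
        marginal = measure_marginal(first, second, universe6)
        closed = measure_closed(first, second, universe6)
        assert brute == pytest.approx(marginal.complete, rel=1e-10)
        for field in ("t1", "t2", "t3"):
            assert getattr(marginal, field) == pytest.approx(
                getattr(closed, field), rel=1e-9, abs=1e-12
            )

    def test_singleton_disjoint_lists(self):
        universe = FeatureUniverse(("a", "b", "c"))
        first = RankedList(("a",))
        second = RankedList(("b",))
        brute = measure_bruteforce(first, second, universe)
        marginal = measure_marginal(first, second, universe)
        assert brute == pytest.approx(marginal.complete, rel=1e-10)

    def test_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            first, second, universe = random_instance(rng, 10**4)
            brute = measure_bruteforce(first, second, universe)
            marginal = measure_marginal(first, second, universe)
            closed = measure_closed(first, second, universe)
            assert brute == pytest.approx(marginal.complete, rel=1e-9, abs=1e-12)
            for field in ("t1", "t2", "t3"):
                assert getattr(marginal, field) == pytest.approx(
                    getattr(closed, field), rel=1e-9, abs=1e-12
                )

    def test_enumeration_cap_refusal_reports_size(self, universe100):
        lst = take(universe100, range(3))
        with pytest.raises(CapabilityError, match="completion pairs"):
            measure_bruteforce(lst, lst, universe100, cap=100)


class TestT3Invariance:
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_t3_depends_only_on_shapes(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(4, 30))
        universe = FeatureUniverse.auto(p)
        l1 = int(rng.integers(1, p))
        l2 = int(rng.integers(1, p))
        s1 = rng.choice(p, size=l1, replace=False)
        s2 = rng.choice(p, size=l2, replace=False)
        base = measure_closed(take(universe, s1), take(universe, s2), universe)
        shuffled = measure_closed(
            take(universe, s1[rng.permutation(l1)]),
            take(universe, s2[rng.permutation(l2)]),
            universe,
        )
        assert base.t3 == shuffled.t3  # bit-identical


class TestNormalize:
    def test_fixed_points(self):
        assert normalize(0.0, 10) == 0.0
        assert normalize(expected_canberra(10), 10) == pytest.approx(1.0, rel=1e-12)

    def test_values_above_one_are_not_clamped(self):
        # the group mean is not the maximum: the farthest permutation pair
        # normalises to a value above 1
        import itertools

        p = 6
        identity = np.arange(1, p + 1)
        top = max(
            canberra_rank_distance(sigma, identity)
            for sigma in itertools.permutations(identity)
        )
        assert normalize(top, p) > 1.0

    def test_requires_p_at_least_two(self):
        with pytest.raises(InputError):
            normalize(1.0, 1)

    def test_breakdown_normalizer_matches_group_mean(self, universe100):
        lst = take(universe100, range(5))
        bd = measure_closed(lst, lst, universe100)
        assert bd.normalizer == pytest.approx(expected_canberra(100), rel=1e-12)


class TestValidation:
    def test_harmonic_table_too_small(self, universe100):
        lst = take(universe100, range(4))
        with pytest.raises(InputError, match="harmonic table"):
            measure_closed(lst, lst, universe100, table=harmonic_numbers(50))
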