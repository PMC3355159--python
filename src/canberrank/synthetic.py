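"""Seeded generators for the benchmark configurations the measures are
calibrated against.

Three ingredients cover every benchmark in the package: uniform random
complete rankings, random partial (top-l) lists with either independent or
shared supports, and the ordering maximally Canberra-distant from the
identity.  All generators are pure functions of their integer seed.

Two driver routines reproduce the package's reference experiments:

- :func:`stability_replicates` — mean and variance over replicates of the
  normalized stability indicator for sets of random complete lists; for
  any (n, p) the indicator concentrates near 1, since the normaliser E(p)
  is exactly the expected pairwise distance.
- :func:`partial_pair_table` — normalized Core/Complete values for an
  identical, a random shared-support, and a maximally distant
  shared-support pair of length-l lists, the worked reference grid for
  partial-list behaviour as the universe grows.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import islice, permutations
from typing import Dict, Tuple

import numpy as np

from .core import canberra_rank_distance, harmonic_numbers
from .errors import CapabilityError, InputError
from .lists import FeatureUniverse, ListSet, RankedList
from .measures import measure_closed
from .stability import stability_indicator

__all__ = [
    "random_complete_lists",
    "random_partial_lists",
    "max_distant_ordering",
    "stability_replicates",
    "partial_pair_table",
]

#: Exhaustive-search bound for the maximally distant ordering (l! orderings).
MAX_SEARCH_LENGTH = 10


def random_complete_lists(n: int, p: int, seed: int) -> ListSet:
    """n independent uniform random permutations of a p-feature universe."""
    if n < 2 or p < 2:
        raise InputError(f"need n >= 2 and p >= 2, got n={n}, p={p}")
    rng = np.random.default_rng(seed)
    universe = FeatureUniverse.auto(p)
    lists = tuple(
        RankedList(tuple(universe.features[i] for i in rng.permutation(p)))
        for _ in range(n)
    )
    return ListSet(universe, lists)


def random_partial_lists(
    n: int, p: int, length: int, seed: int, shared_support: bool = False
) -> ListSet:
    """n random top-``length`` lists over a p-feature universe.

    With ``shared_support`` one support of ``length`` features is drawn
    once and each list is an independent uniform ordering of it; otherwise
    every list draws support and order independently (a uniform random
    ``length``-prefix of a permutation).
    """
    if n < 1 or p < 1 or length < 0 or length > p:
        raise InputError(
            f"invalid sizes: n={n}, p={p}, list length={length} (need length <= p)"
        )
    rng = np.random.default_rng(seed)
    universe = FeatureUniverse.auto(p)
    lists = []
    support = rng.choice(p, size=length, replace=False) if shared_support else None
    for _ in range(n):
        if shared_support:
            idx = support[rng.permutation(length)]
        else:
            idx = rng.choice(p, size=length, replace=False)
        lists.append(RankedList(tuple(universe.features[i] for i in idx)))
    return ListSet(universe, tuple(lists))


@lru_cache(maxsize=None)
def max_distant_ordering(length: int, bound: int = MAX_SEARCH_LENGTH) -> Tuple[int, ...]:
    """Ordering of 1..l maximising the Canberra distance to the identity.

    Exhaustive search over all l! orderings (chunked, vectorised), capped
    at ``bound`` because the search is factorial; ties go to the
    lexicographically first maximiser.  By right-invariance this single
    ordering realises the maximally distant pair for *any* shared support
    of size l, whatever the enclosing universe.
    """
    if length < 1:
        raise InputError(f"list length must be >= 1, got {length}")
    if length > bound:
        raise CapabilityError(
            f"exhaustive search over {length}! orderings exceeds the bound "
            f"of {bound}; use a construction from the rank-distance "
            "literature for longer lists"
        )
    identity = np.arange(1, length + 1, dtype=float)
    best_value = -1.0
    best: Tuple[int, ...] = tuple(range(1, length + 1))
    perms = permutations(range(1, length + 1))
    while True:
        chunk = list(islice(perms, 120_000))
        if not chunk:
            break
        arr = np.asarray(chunk, dtype=float)
        dist = np.sum(np.abs(arr - identity) / (arr + identity), axis=1)
        k = int(np.argmax(dist))
        if dist[k] > best_value:
            best_value = float(dist[k])
            best = tuple(chunk[k])
    return best


def stability_replicates(
    n_lists: int, p: int, replicates: int, seed: int
) -> Tuple[float, float]:
    """Mean and (sample) variance over replicates of the normalized
    complete-mode stability indicator for sets of random complete lists."""
    if replicates < 2:
        raise InputError("variance needs at least 2 replicates")
    child_seeds = np.random.SeedSequence(seed).spawn(replicates)
    values = []
    for child in child_seeds:
        rep_seed = int(child.generate_state(1)[0] % 2**31)
        list_set = random_complete_lists(n_lists, p, rep_seed)
        values.append(stability_indicator(list_set, "complete", normalized=True))
    arr = np.asarray(values)
    return float(arr.mean()), float(arr.var(ddof=1))


def partial_pair_table(p: int, length: int, seed: int) -> Dict[str, Dict[str, float]]:
    """Normalized Core/Complete values for three reference pairs of
    length-``length`` lists sharing one support inside a p-feature universe.

    Rows: ``identical`` (Core is exactly 0; Complete is positive, driven
    by the unselected features), ``random`` (one random pair of orderings
    — a single draw, not an expectation), and ``max_distant`` (the
    exhaustive-search maximiser).  ``max_distant`` Complete equals
    ``identical`` Complete plus ``max_distant`` Core, since the
    unselected-feature term only depends on the support sizes.
    """
    if not 1 <= length <= p:
        raise InputError(f"need 1 <= length <= p, got length={length}, p={p}")
    universe = FeatureUniverse.auto(p)
    table = harmonic_numbers(2 * p)
    rng = np.random.default_rng(seed)

    base = RankedList(universe.features[:length])

    def reordered(order_1based) -> RankedList:
        return RankedList(tuple(universe.features[r - 1] for r in order_1based))

    random_pair = reordered(rng.permutation(length) + 1)
    max_pair = reordered(max_distant_ordering(length))

    rows: Dict[str, Dict[str, float]] = {}
    for name, other in (
        ("identical", base),
        ("random", random_pair),
        ("max_distant", max_pair),
    ):
        bd = measure_closed(base, other, universe, table)
        rows[name] = {
            "core": bd.core_normalized,
            "complete": bd.complete_normalized,
        }
    return rows


def max_rank_distance(length: int) -> float:
    """Maximum Canberra distance between two orderings of l shared items."""
    sigma = np.asarray(max_distant_ordering(length), dtype=float)
    return canberra_rank_distance(sigma, np.arange(1, length + 1, dtype=float))
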