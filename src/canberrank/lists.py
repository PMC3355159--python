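"""Containers for feature universes and partial ranked lists.

A :class:`FeatureUniverse` is the full alphabet of p distinct feature
identifiers an experiment starts from (probes, genes, ...).  A
:class:`RankedList` is an ordered, duplicate-free selection of l <= p of
them — a top-l list, rank 1 being the most important.  A :class:`ListSet`
bundles B such lists over one shared universe, the input shape of the
stability indicator and of Borda aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Sequence, Tuple

import numpy as np

from .errors import InputError

__all__ = [
    "FeatureUniverse",
    "RankedList",
    "ListSet",
    "SupportPartition",
    "dualize",
    "partition_support",
]


@dataclass(frozen=True)
class FeatureUniverse:
    """Ordered alphabet of distinct feature identifiers."""

    features: Tuple[str, ...]
    _index: Dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        feats = tuple(self.features)
        if not feats:
            raise InputError("a feature universe must contain at least one feature")
        index = {f: i for i, f in enumerate(feats)}
        if len(index) != len(feats):
            raise InputError("feature universe contains duplicate identifiers")
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "_index", index)

    @property
    def size(self) -> int:
        return len(self.features)

    def __contains__(self, feature: str) -> bool:
        return feature in self._index

    def __len__(self) -> int:
        return len(self.features)

    def index(self, feature: str) -> int:
        """Position of ``feature`` in universe order (0-based)."""
        try:
            return self._index[feature]
        except KeyError:
            raise InputError(f"feature {feature!r} is not in the universe") from None

    @classmethod
    def auto(cls, p: int, prefix: str = "f") -> "FeatureUniverse":
        """Universe of ``p`` auto-named features ``f000001 .. f<p>``.

        The zero-padded names keep lexicographic order equal to universe
        order, so downstream tie-breaks stay deterministic.
        """
        if p < 1:
            raise InputError(f"universe size must be >= 1, got {p}")
        width = max(6, len(str(p)))
        return cls(tuple(f"{prefix}{i:0{width}d}" for i in range(1, p + 1)))


@dataclass(frozen=True)
class RankedList:
    """Ordered, duplicate-free partial list; ``items[k]`` has rank ``k + 1``."""

    items: Tuple[str, ...]

    def __post_init__(self) -> None:
        items = tuple(self.items)
        if len(set(items)) != len(items):
            dupes = sorted({f for f in items if items.count(f) > 1})
            raise InputError(f"ranked list contains duplicate feature(s): {dupes}")
        object.__setattr__(self, "items", items)

    @property
    def length(self) -> int:
        return len(self.items)

    def __len__(self) -> int:
        return len(self.items)

    def validate(self, universe: FeatureUniverse) -> None:
        for f in self.items:
            if f not in universe:
                raise InputError(f"feature {f!r} is not in the universe")
        if len(self.items) > universe.size:
            raise InputError("ranked list is longer than the universe")


@dataclass(frozen=True)
class ListSet:
    """B ranked lists over one shared universe; lengths may differ."""

    universe: FeatureUniverse
    lists: Tuple[RankedList, ...]

    def __post_init__(self) -> None:
        lists = tuple(self.lists)
        for lst in lists:
            lst.validate(self.universe)
        object.__setattr__(self, "lists", lists)

    @property
    def n_lists(self) -> int:
        return len(self.lists)

    def __len__(self) -> int:
        return len(self.lists)


@dataclass(frozen=True)
class SupportPartition:
    """Disjoint split of the universe induced by a pair of lists.

    ``common`` holds the z features present in both lists, ``only_first``
    and ``only_second`` the features exclusive to one list, and
    ``unselected_count`` the u = p - (l1 + l2 - z) features in neither.
    """

    common: frozenset
    only_first: frozenset
    only_second: frozenset
    unselected_count: int

    @property
    def z(self) -> int:
        return len(self.common)


def dualize(ranked: RankedList, universe: FeatureUniverse) -> Dict[str, int]:
    """Rank assignment of a list: feature -> 1-based position.

    Features not in the list are simply absent from the mapping (no
    sentinel rank); for a complete list the values are a permutation of
    ``1..p``.
    """
    ranked.validate(universe)
    return {f: k + 1 for k, f in enumerate(ranked.items)}


def partition_support(
    first: RankedList, second: RankedList, universe: FeatureUniverse
) -> SupportPartition:
    """Split the universe into both/one/neither sets for a pair of lists."""
    first.validate(universe)
    second.validate(universe)
    s1, s2 = set(first.items), set(second.items)
    common = s1 & s2
    u = universe.size - len(s1 | s2)
    return SupportPartition(
        common=frozenset(common),
        only_first=frozenset(s1 - common),
        only_second=frozenset(s2 - common),
        unselected_count=u,
    )


def as_ranked_lists(
    universe: FeatureUniverse, rows: Iterable[Sequence[str]]
) -> ListSet:
    """Build a validated :class:`ListSet` from raw token sequences."""
    return ListSet(universe, tuple(RankedList(tuple(row)) for row in rows))


def rank_matrix(list_set: ListSet) -> np.ndarray:
    """Dense B x p matrix of ranks, 0 where a feature is unlisted.

    Convenience for vectorised consumers (stability on complete lists,
    Borda statistics); 0 is a placeholder, not a rank.
    """
    p = list_set.universe.size
    out = np.zeros((list_set.n_lists, p), dtype=np.int64)
    for b, lst in enumerate(list_set.lists):
        for k, f in enumerate(lst.items):
            out[b, list_set.universe.index(f)] = k + 1
    return out
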