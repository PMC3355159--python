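"""Borda aggregation of a set of ranked lists into one optimal list.

Each feature is scored by its number of extractions (how many lists
contain it) and, among those lists, its mean 1-based position.  Features
are ordered by decreasing extractions, ties by increasing mean position,
residual ties by universe order — a total, deterministic rule.  On
complete lists this reduces to the classical Borda count: ordering by
ascending total rank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

from .lists import ListSet, RankedList

__all__ = ["BordaEntry", "BordaList", "extraction_stats", "borda_list"]


@dataclass(frozen=True)
class BordaEntry:
    """Aggregation statistics for one feature.

    ``mean_position`` is averaged only over the lists that contain the
    feature and is ``None`` when no list does.
    """

    feature: str
    extractions: int
    mean_position: Optional[float]


@dataclass(frozen=True)
class BordaList:
    """Entries in Borda order; ``ranking`` is the bare feature sequence."""

    entries: Tuple[BordaEntry, ...]

    @property
    def ranking(self) -> Tuple[str, ...]:
        return tuple(e.feature for e in self.entries)

    def as_ranked_list(self) -> RankedList:
        return RankedList(self.ranking)

    def __len__(self) -> int:
        return len(self.entries)


def extraction_stats(list_set: ListSet) -> Tuple[BordaEntry, ...]:
    """Per-feature extraction count and mean position, in universe order."""
    counts = {f: 0 for f in list_set.universe.features}
    position_sums = {f: 0 for f in list_set.universe.features}
    for lst in list_set.lists:
        for k, f in enumerate(lst.items):
            counts[f] += 1
            position_sums[f] += k + 1
    return tuple(
        BordaEntry(
            feature=f,
            extractions=counts[f],
            mean_position=position_sums[f] / counts[f] if counts[f] else None,
        )
        for f in list_set.universe.features
    )


def borda_list(list_set: ListSet, include_unextracted: bool = False) -> BordaList:
    """Aggregate a list set by the Borda rule.

    Features extracted by no list are omitted by default; with
    ``include_unextracted`` they are appended after every extracted
    feature, in universe order.
    """
    entries = extraction_stats(list_set)

    def key(item):
        index, entry = item
        mean_pos = entry.mean_position if entry.mean_position is not None else math.inf
        return (-entry.extractions, mean_pos, index)

    ordered = [e for _, e in sorted(enumerate(entries), key=key)]
    if not include_unextracted:
        ordered = [e for e in ordered if e.extractions > 0]
    return BordaList(tuple(ordered))
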