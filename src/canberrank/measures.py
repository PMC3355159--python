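"""Complete and Core Canberra measures between partial ranked lists.

Two top-l lists over a p-feature universe do not determine a unique pair of
permutations: a length-l list has (p - l)! completions, one per way of
arranging the unlisted features over the bottom positions.  The measure is
defined as the *mean* Canberra distance over all pairs of completions.  By
linearity of expectation over independent uniform completions that mean
splits into three terms:

- T1, features in both lists: the plain Canberra summand on their two
  known ranks;
- T2, features in exactly one list: the known rank r against the uniform
  average over the other list's bottom positions l_other+1 .. p;
- T3, features in neither list: u times the average summand over the
  bottom-position rectangle — it depends only on (p, l1, l2) and the size
  u of the unselected set, never on which features were picked.

Core = T1 + T2 keeps only the position-dependent part; Complete adds T3.
Complete is *not* a metric: two identical partial lists with l < p sit at a
positive Complete distance, because their completions differ.  Values are
usually reported after dividing by the group mean E(p), and normalized
values above 1 are legal (E(p) is a mean, not the maximum).

Three interchangeable strategies are exposed.  ``measure_bruteforce``
enumerates completions (the defining semantics, feasible only for tiny
problems), ``measure_marginal`` evaluates the per-feature expectation form
above by direct summation, and ``measure_closed`` evaluates the same
quantities through harmonic-number identities in O(l1 + l2) work after an
O(p) table build — the production path, fine at p = 10^5 and beyond.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Optional

import numpy as np

from .core import (
    abs_ratio_range_sum,
    abs_ratio_rectangle_sum,
    expected_canberra,
    harmonic_numbers,
)
from .errors import CapabilityError, InputError
from .lists import FeatureUniverse, RankedList, dualize, partition_support

__all__ = [
    "DistanceBreakdown",
    "measure_marginal",
    "measure_closed",
    "measure_bruteforce",
    "normalize",
]

#: Largest number of completion pairs measure_bruteforce accepts by default.
DEFAULT_ENUMERATION_CAP = 10**6


@dataclass(frozen=True)
class DistanceBreakdown:
    """Componentwise result of a partial-list comparison.

    ``core = t1 + t2`` and ``complete = core + t3`` hold exactly (same
    summation order).  ``normalizer`` is E(p); the normalized fields are
    NaN when p < 2, where E(p) = 0 and normalisation is undefined.
    """

    t1: float
    t2: float
    t3: float
    normalizer: float

    @property
    def core(self) -> float:
        return self.t1 + self.t2

    @property
    def complete(self) -> float:
        return (self.t1 + self.t2) + self.t3

    @property
    def core_normalized(self) -> float:
        return self.core / self.normalizer if self.normalizer > 0 else math.nan

    @property
    def complete_normalized(self) -> float:
        return self.complete / self.normalizer if self.normalizer > 0 else math.nan

    def value(self, mode: str = "complete", normalized: bool = True) -> float:
        """Pick one number out of the breakdown."""
        if mode not in ("complete", "core"):
            raise InputError(f"mode must be 'complete' or 'core', got {mode!r}")
        if normalized:
            return self.complete_normalized if mode == "complete" else self.core_normalized
        return self.complete if mode == "complete" else self.core


def normalize(value: float, p: int) -> float:
    """Divide a raw measure by the group mean E(p).

    No clamping: values above 1 are meaningful (farther apart than two
    random complete rankings on average).
    """
    if p < 2:
        raise InputError("normalisation needs p >= 2 (E(1) = 0)")
    if value < 0:
        raise InputError("measure values are nonnegative")
    return value / expected_canberra(p)


def _normalizer(p: int) -> float:
    return expected_canberra(p) if p >= 2 else 0.0


def _t3_term(p: int, l1: int, l2: int, u: int, table: np.ndarray) -> float:
    """u * mean Canberra summand over the bottom rectangle
    (l1+1..p) x (l2+1..p), by inclusion-exclusion on four corner sums."""
    if u == 0 or p == l1 or p == l2:
        return 0.0
    rect = (
        abs_ratio_rectangle_sum(p, p, table)
        - abs_ratio_rectangle_sum(l1, p, table)
        - abs_ratio_rectangle_sum(p, l2, table)
        + abs_ratio_rectangle_sum(l1, l2, table)
    )
    # the rectangle is a sum of nonnegative terms; inclusion-exclusion can
    # cancel to a tiny negative float when the true value is near zero
    rect = max(rect, 0.0)
    return u * rect / ((p - l1) * (p - l2))


def measure_closed(
    first: RankedList,
    second: RankedList,
    universe: FeatureUniverse,
    table: Optional[np.ndarray] = None,
) -> DistanceBreakdown:
    """Harmonic closed form of the partial-list measure.

    O(l1 + l2) per pair once a harmonic table covering 2p is available;
    pass ``table`` explicitly to amortise it over many pairs (as the
    stability indicator does).
    """
    p = universe.size
    if table is None:
        table = harmonic_numbers(2 * p)
    elif table.size - 1 < 2 * p:
        raise InputError(
            f"harmonic table too small: need index {2 * p}, have {table.size - 1}"
        )
    tau1 = dualize(first, universe)
    tau2 = dualize(second, universe)
    part = partition_support(first, second, universe)
    l1, l2 = first.length, second.length

    t1 = 0.0
    if part.common:
        r1 = np.array([tau1[f] for f in sorted(part.common)], dtype=float)
        r2 = np.array([tau2[f] for f in sorted(part.common)], dtype=float)
        t1 = float(np.sum(np.abs(r1 - r2) / (r1 + r2)))

    t2 = 0.0
    if part.only_first:
        ranks = np.array([tau1[f] for f in sorted(part.only_first)])
        t2 += float(np.sum(abs_ratio_range_sum(ranks, l2 + 1, p, table))) / (p - l2)
    if part.only_second:
        ranks = np.array([tau2[f] for f in sorted(part.only_second)])
        t2 += float(np.sum(abs_ratio_range_sum(ranks, l1 + 1, p, table))) / (p - l1)

    t3 = _t3_term(p, l1, l2, part.unselected_count, table)
    return DistanceBreakdown(t1=t1, t2=t2, t3=t3, normalizer=_normalizer(p))


def measure_marginal(
    first: RankedList, second: RankedList, universe: FeatureUniverse
) -> DistanceBreakdown:
    """Per-feature expectation form, evaluated by direct summation.

    Same contract and results as :func:`measure_closed`, but each T2 term
    is an explicit O(p) sum and T3 an explicit double sum — the readable
    reference the closed form is checked against.
    """
    p = universe.size
    tau1 = dualize(first, universe)
    tau2 = dualize(second, universe)
    part = partition_support(first, second, universe)
    l1, l2 = first.length, second.length

    t1 = sum(
        abs(tau1[f] - tau2[f]) / (tau1[f] + tau2[f]) for f in sorted(part.common)
    )

    t2 = 0.0
    for f in sorted(part.only_first):
        r = tau1[f]
        j = np.arange(l2 + 1, p + 1, dtype=float)
        t2 += float(np.sum(np.abs(r - j) / (r + j))) / (p - l2)
    for f in sorted(part.only_second):
        r = tau2[f]
        j = np.arange(l1 + 1, p + 1, dtype=float)
        t2 += float(np.sum(np.abs(r - j) / (r + j))) / (p - l1)

    u = part.unselected_count
    if u == 0:
        t3 = 0.0
    else:
        i = np.arange(l1 + 1, p + 1, dtype=float)[:, None]
        j = np.arange(l2 + 1, p + 1, dtype=float)[None, :]
        t3 = u * float(np.sum(np.abs(i - j) / (i + j))) / ((p - l1) * (p - l2))
    return DistanceBreakdown(t1=t1, t2=t2, t3=t3, normalizer=_normalizer(p))


def _completions(ranked: RankedList, universe: FeatureUniverse) -> np.ndarray:
    """All dual rank vectors of the completions of a partial list.

    Rows are completions, columns follow universe order; listed features
    keep their rank, the (p - l)! arrangements of the rest fill the bottom.
    """
    p = universe.size
    tau = dualize(ranked, universe)
    missing = [f for f in universe.features if f not in tau]
    base = np.zeros(p, dtype=np.int64)
    for f, r in tau.items():
        base[universe.index(f)] = r
    bottom = np.arange(ranked.length + 1, p + 1, dtype=np.int64)
    rows = []
    for perm in permutations(range(len(missing))):
        row = base.copy()
        for slot, which in enumerate(perm):
            row[universe.index(missing[which])] = bottom[slot]
        rows.append(row)
    return np.array(rows, dtype=float)


def measure_bruteforce(
    first: RankedList,
    second: RankedList,
    universe: FeatureUniverse,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> float:
    """Defining semantics: mean Canberra distance over every pair of
    completions, by explicit enumeration.

    Returns the Complete measure (raw).  Refuses when the enumeration
    exceeds ``cap`` completion pairs.
    """
    p = universe.size
    first.validate(universe)
    second.validate(universe)
    n1 = math.factorial(p - first.length)
    n2 = math.factorial(p - second.length)
    if n1 * n2 > cap:
        raise CapabilityError(
            f"enumeration needs {n1} x {n2} = {n1 * n2} completion pairs, "
            f"above the cap of {cap}"
        )
    d1 = _completions(first, universe)
    d2 = _completions(second, universe)
    # pairwise Canberra distances via broadcasting, chunked over d1 rows
    total = 0.0
    step = max(1, int(2e7 // (d2.shape[0] * p + 1)))
    for start in range(0, d1.shape[0], step):
        block = d1[start : start + step][:, None, :]
        total += float(np.sum(np.abs(block - d2[None]) / (block + d2[None])))
    return total / (n1 * n2)
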