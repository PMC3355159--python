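"""List-stability indicator: mean mutual dissimilarity of a set of lists.

Given B ranked lists produced by, say, the resampling runs of a feature
selection pipeline, the indicator is the mean of the B(B-1)/2 pairwise
measures — the smaller, the more self-homogeneous the set.  Diagonal
(self) values are computed and reported, because Complete(L, L) > 0 for a
partial list is informative in itself, but they never enter the mean: for
random complete lists the pair-mean convention concentrates the normalized
indicator near 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import expected_canberra, harmonic_numbers
from .errors import InputError
from .lists import ListSet
from .measures import measure_closed

__all__ = [
    "StabilityReport",
    "pairwise_matrix",
    "stability_indicator",
    "stability_report",
]


@dataclass(frozen=True)
class StabilityReport:
    """Pairwise matrix plus its summary indicator."""

    matrix: np.ndarray
    indicator: float
    mode: str
    normalized: bool
    normalizer: float

    @property
    def n_lists(self) -> int:
        return self.matrix.shape[0]


def _check(list_set: ListSet, mode: str) -> None:
    if list_set.n_lists < 2:
        raise InputError(f"need at least 2 lists, got {list_set.n_lists}")
    if mode not in ("complete", "core"):
        raise InputError(f"mode must be 'complete' or 'core', got {mode!r}")


def pairwise_matrix(
    list_set: ListSet, mode: str = "complete", normalized: bool = True
) -> np.ndarray:
    """Symmetric B x B matrix of measure values (closed-form evaluation).

    The diagonal holds self-dissimilarities: zero in core mode, positive
    in complete mode whenever a list is partial.
    """
    _check(list_set, mode)
    p = list_set.universe.size
    table = harmonic_numbers(2 * p)
    b = list_set.n_lists
    out = np.zeros((b, b))
    for i in range(b):
        for j in range(i, b):
            bd = measure_closed(
                list_set.lists[i], list_set.lists[j], list_set.universe, table
            )
            out[i, j] = out[j, i] = bd.value(mode, normalized)
    return out


def stability_indicator(
    list_set: ListSet, mode: str = "complete", normalized: bool = True
) -> float:
    """Mean over the unordered distinct pairs of the pairwise matrix."""
    matrix = pairwise_matrix(list_set, mode, normalized)
    iu = np.triu_indices(matrix.shape[0], k=1)
    return float(matrix[iu].mean())


def stability_report(
    list_set: ListSet, mode: str = "complete", normalized: bool = True
) -> StabilityReport:
    """Matrix and indicator in one pass."""
    matrix = pairwise_matrix(list_set, mode, normalized)
    iu = np.triu_indices(matrix.shape[0], k=1)
    p = list_set.universe.size
    return StabilityReport(
        matrix=matrix,
        indicator=float(matrix[iu].mean()),
        mode=mode,
        normalized=normalized,
        normalizer=expected_canberra(p) if p >= 2 else 0.0,
    )
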