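"""Plain-text input/output for ranked lists and reports.

Ranked-list files hold one list per line, tokens separated by tabs or
commas; blank lines and lines starting with ``#`` are ignored.  A feature
universe is either an explicit file (one feature per line) or implicit —
because the measures depend on feature identity only through list
membership, a bare universe *size* is enough, and features are then
auto-named ``f000001, f000002, ...``.

All serialisation is deterministic: floats are printed with a fixed
number of decimals (6 by default) and JSON keys are emitted in a fixed
order, so identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import json
from typing import List, Optional, Sequence, Union

import numpy as np

from .borda import BordaList
from .errors import InputError
from .lists import FeatureUniverse, ListSet, RankedList
from .measures import DistanceBreakdown
from .stability import StabilityReport

__all__ = [
    "read_universe",
    "read_ranked_lists",
    "write_ranked_lists",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_report",
    "report_to_text",
]


def _data_lines(path) -> List[tuple]:
    try:
        with open(path, "r", encoding="utf-8") as handle:
            raw = handle.readlines()
    except OSError as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc
    lines = []
    for lineno, line in enumerate(raw, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        lines.append((lineno, stripped))
    return lines


def read_universe(path) -> FeatureUniverse:
    """Universe file: one feature identifier per line."""
    lines = _data_lines(path)
    if not lines:
        raise InputError(f"universe file {path} contains no features")
    return FeatureUniverse(tuple(token for _, token in lines))


def _split(line: str, dialect: Optional[str]) -> List[str]:
    if dialect is None:
        dialect = "\t" if "\t" in line else ","
    return [tok.strip() for tok in line.split(dialect) if tok.strip()]


def read_ranked_lists(
    path,
    universe: FeatureUniverse,
    dialect: Optional[str] = None,
    has_ids: bool = False,
) -> ListSet:
    """Parse a ranked-list file into a validated :class:`ListSet`.

    ``dialect`` is the token separator (``"\\t"`` or ``","``; auto-detected
    per line when omitted).  With ``has_ids`` the first token of each line
    is a list label and is dropped.
    """
    lines = _data_lines(path)
    if not lines:
        raise InputError(f"ranked-list file {path} contains no lists")
    lists = []
    for lineno, line in enumerate_tokens(lines, dialect, has_ids):
        seen = set()
        for token in line:
            if token in seen:
                raise InputError(
                    f"{path}, line {lineno}: duplicate feature {token!r}"
                )
            seen.add(token)
            if token not in universe:
                raise InputError(
                    f"{path}, line {lineno}: feature {token!r} is not in the universe"
                )
        lists.append(RankedList(tuple(line)))
    return ListSet(universe, tuple(lists))


def enumerate_tokens(lines, dialect, has_ids):
    for lineno, line in lines:
        tokens = _split(line, dialect)
        if has_ids:
            tokens = tokens[1:]
        yield lineno, tokens


def write_ranked_lists(list_set: ListSet, path, dialect: str = "\t") -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for lst in list_set.lists:
            handle.write(dialect.join(lst.items) + "\n")


def write_matrix_tsv(
    matrix: np.ndarray,
    path,
    labels: Optional[Sequence[str]] = None,
    decimals: int = 6,
) -> None:
    """Symmetric pairwise matrix as TSV with a label header column."""
    b = matrix.shape[0]
    labels = list(labels) if labels is not None else [f"list{i + 1}" for i in range(b)]
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join([""] + labels) + "\n")
        for i in range(b):
            row = "\t".join(f"{matrix[i, j]:.{decimals}f}" for j in range(b))
            handle.write(f"{labels[i]}\t{row}\n")


def read_matrix_tsv(path) -> np.ndarray:
    rows = []
    with open(path, "r", encoding="utf-8") as handle:
        header = handle.readline()
        if not header.strip():
            raise InputError(f"matrix file {path} is empty")
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            rows.append([float(x) for x in parts[1:]])
    return np.asarray(rows)


Report = Union[StabilityReport, BordaList, DistanceBreakdown]


def _report_dict(report: Report, seed: Optional[int], decimals: int) -> dict:
    rnd = lambda x: None if x is None else round(float(x), decimals)
    if isinstance(report, StabilityReport):
        return {
            "kind": "stability",
            "mode": report.mode,
            "normalized": report.normalized,
            "normalizer": rnd(report.normalizer),
            "n_lists": report.n_lists,
            "indicator": rnd(report.indicator),
            "matrix": [[rnd(v) for v in row] for row in report.matrix],
            "seed": seed,
        }
    if isinstance(report, BordaList):
        return {
            "kind": "borda",
            "entries": [
                {
                    "feature": e.feature,
                    "extractions": e.extractions,
                    "mean_position": rnd(e.mean_position),
                    "borda_rank": rank,
                }
                for rank, e in enumerate(report.entries, start=1)
            ],
            "seed": seed,
        }
    if isinstance(report, DistanceBreakdown):
        return {
            "kind": "distance",
            "t1": rnd(report.t1),
            "t2": rnd(report.t2),
            "t3": rnd(report.t3),
            "core": rnd(report.core),
            "complete": rnd(report.complete),
            "normalizer": rnd(report.normalizer),
            "core_normalized": rnd(report.core_normalized),
            "complete_normalized": rnd(report.complete_normalized),
            "seed": seed,
        }
    raise InputError(f"unsupported report object: {type(report).__name__}")


def report_to_text(
    report: Report,
    format: str = "tsv",
    seed: Optional[int] = None,
    decimals: int = 6,
) -> str:
    """Serialise a report deterministically to TSV or JSON text."""
    if format == "json":
        return json.dumps(_report_dict(report, seed, decimals), indent=2) + "\n"
    if format != "tsv":
        raise InputError(f"format must be 'tsv' or 'json', got {format!r}")
    fmt = lambda x: f"{float(x):.{decimals}f}"
    if isinstance(report, StabilityReport):
        lines = [
            f"indicator\t{fmt(report.indicator)}",
            f"mode\t{report.mode}",
            f"normalized\t{report.normalized}",
            f"normalizer\t{fmt(report.normalizer)}",
            f"n_lists\t{report.n_lists}",
        ]
        return "\n".join(lines) + "\n"
    if isinstance(report, BordaList):
        lines = ["feature\textractions\tmean_position\tborda_rank"]
        for rank, e in enumerate(report.entries, start=1):
            mean_pos = "" if e.mean_position is None else fmt(e.mean_position)
            lines.append(f"{e.feature}\t{e.extractions}\t{mean_pos}\t{rank}")
        return "\n".join(lines) + "\n"
    if isinstance(report, DistanceBreakdown):
        lines = [
            f"t1\t{fmt(report.t1)}",
            f"t2\t{fmt(report.t2)}",
            f"t3\t{fmt(report.t3)}",
            f"core\t{fmt(report.core)}",
            f"complete\t{fmt(report.complete)}",
            f"normalizer\t{fmt(report.normalizer)}",
            f"core_normalized\t{fmt(report.core_normalized)}",
            f"complete_normalized\t{fmt(report.complete_normalized)}",
        ]
        return "\n".join(lines) + "\n"
    raise InputError(f"unsupported report object: {type(report).__name__}")


def write_report(
    report: Report,
    path,
    format: str = "tsv",
    seed: Optional[int] = None,
    decimals: int = 6,
) -> None:
    text = report_to_text(report, format=format, seed=seed, decimals=decimals)
    try:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(text)
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc
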