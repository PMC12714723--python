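"""Partition extracted spacers into duplicates of existing spacers vs. new acquisitions.

An extracted spacer that matches any spacer already present in the original
CRISPR arrays, allowing up to ten mismatches, is a duplicate — the product
of rearrangement of existing spacers — and only spacers with no such
resemblance count as new acquisitions.  Both strands are compared, because
the orientation of an extracted insert is not guaranteed to match the
orientation in which the arrays were deposited.

Distance metric: Hamming distance for equal-length pairs and unit-cost edit
distance (substitutions and indels) when lengths differ ("auto", the
default).  The screen can be forced to pure edit distance with
``metric="edit"`` or to equal-length-only Hamming with ``metric="hamming"``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .extraction import CrisprArray
from .fileio import revcomp

#: A spacer within this many mismatches of an existing spacer is a duplicate.
DEFAULT_MAX_MISMATCHES = 10

_INF = 10**9


def _hamming(a: str, b: str) -> int:
    arr_a = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    return int((arr_a != arr_b).sum())


def _pair_distance(query: str, target: str, metric: str) -> int:
    if metric == "hamming":
        return _hamming(query, target) if len(query) == len(target) else _INF
    if metric == "edit" or len(query) != len(target):
        return edlib.align(query, target, mode="NW", task="distance")["editDistance"]
    return _hamming(query, target)


def spacer_distance(query: str, target: str, metric: str = "auto") -> int:
    """Minimum comparison distance between a query spacer and an array spacer.

    The target is compared on both strands and the smaller distance returned.
    """
    if metric not in ("auto", "edit", "hamming"):
        raise ValueError(f"unknown metric {metric!r}")
    return min(
        _pair_distance(query, target, metric),
        _pair_distance(query, revcomp(target), metric),
    )


@dataclass
class ClassifiedSpacer:
    """One extracted spacer labelled duplicate or new."""

    read_id: str
    array_id: str
    sequence: str
    label: str  # duplicate | new
    best_array: str | None
    best_index: int | None
    distance: int | None


@dataclass
class AcquisitionStats:
    """Per-array acquisition summary.

    ``new_to_duplicate_ratio`` is ``n_new / n_duplicate`` and undefined
    (``None``) when the array has no duplicates; it is never reported as
    infinity.  ``fraction_multi_mutated`` is the fraction of duplicates
    carrying two or more mismatches.
    """

    array_id: str
    n_new: int
    n_duplicate: int
    new_to_duplicate_ratio: float | None
    duplicate_mutation_histogram: dict[int, int] = field(default_factory=dict)
    fraction_multi_mutated: float = 0.0


def classify_spacer(
    sequence: str,
    arrays: Sequence[CrisprArray],
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    metric: str = "auto",
) -> tuple[str, str | None, int | None, int]:
    """Classify one spacer against all original arrays.

    Returns ``(label, best_array, best_index, distance)`` where distance is
    the minimum over every existing spacer on both strands.  Ties at the
    minimum are broken deterministically by (array order, spacer index).
    """
    if not arrays:
        raise ValueError("no CRISPR arrays supplied")
    best: tuple[int, int, int] | None = None  # (distance, array pos, spacer index)
    for a_pos, array in enumerate(arrays):
        for s_idx, target in enumerate(array.spacers):
            d = spacer_distance(sequence, target, metric)
            key = (d, a_pos, s_idx)
            if best is None or key < best:
                best = key
    distance, a_pos, s_idx = best
    if distance <= max_mismatches:
        return "duplicate", arrays[a_pos].array_id, s_idx, distance
    return "new", None, None, distance


def classify_spacers(
    extracted: pd.DataFrame,
    arrays: Sequence[CrisprArray],
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    metric: str = "auto",
) -> pd.DataFrame:
    """Classify every kept spacer of an extraction table.

    Expects the frame produced by :func:`adaptscan.extraction.extract_spacers`
    and returns one row per kept spacer with columns ``read_id, array_id,
    sequence, label, best_array, best_index, distance``.  Identical spacer
    sequences share one classification (memoised), which keeps large
    duplicate-dominated assays fast.
    """
    kept = extracted[extracted["status"] == "kept"]
    cache: dict[str, tuple[str, str | None, int | None, int]] = {}
    rows = []
    for read_id, amplicon_array, seq in zip(kept["read_id"], kept["array_id"], kept["spacer"]):
        if seq not in cache:
            cache[seq] = classify_spacer(seq, arrays, max_mismatches, metric)
        label, best_array, best_index, distance = cache[seq]
        rows.append((read_id, amplicon_array, seq, label, best_array, best_index, distance))
    return pd.DataFrame(
        rows,
        columns=["read_id", "array_id", "sequence", "label",
                 "best_array", "best_index", "distance"],
    )


def mutation_spectrum(classified: pd.DataFrame) -> tuple[dict[int, int], float]:
    """Histogram of duplicate distances and the fraction with >= 2 mismatches."""
    duplicates = classified[classified["label"] == "duplicate"]
    histogram = {
        int(k): int(v)
        for k, v in duplicates["distance"].value_counts().sort_index().items()
    }
    n_dup = len(duplicates)
    multi = sum(v for k, v in histogram.items() if k >= 2)
    fraction = multi / n_dup if n_dup else 0.0
    return histogram, fraction


def acquisition_stats(classified: pd.DataFrame) -> dict[str, AcquisitionStats]:
    """Per-array counts, new:duplicate ratio and duplicate mutation spectrum.

    Spacers are attributed to the array whose amplicon they were extracted
    from.  Arrays without duplicates report an undefined (``None``) ratio.
    """
    stats: dict[str, AcquisitionStats] = {}
    for array_id, group in classified.groupby("array_id", sort=True):
        n_new = int((group["label"] == "new").sum())
        histogram, fraction_multi = mutation_spectrum(group)
        n_dup = int((group["label"] == "duplicate").sum())
        ratio = (n_new / n_dup) if n_dup else None
        stats[array_id] = AcquisitionStats(
            array_id, n_new, n_dup, ratio, histogram, fraction_multi
        )
    return stats


def stats_frame(stats: Mapping[str, AcquisitionStats]) -> pd.DataFrame:
    """Flatten per-array stats for TSV output."""
    rows = [
        (s.array_id, s.n_new, s.n_duplicate, s.new_to_duplicate_ratio,
         s.fraction_multi_mutated)
        for s in stats.values()
    ]
    return pd.DataFrame(
        rows,
        columns=["array_id", "n_new", "n_duplicate",
                 "new_to_duplicate_ratio", "fraction_multi_mutated"],
    )
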