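"""Spacer extraction from merged repeat-spacer amplicon reads.

A spacer-acquisition amplicon spans the region between the CRISPR leader and
the third spacer of an array.  A read with the baseline number of repeats
carries no new spacer; a read with one extra repeat carries one inserted
spacer-repeat unit at the leader end, and the inserted spacer is the sequence
strictly between the two repeats closest to the leader.

The operations here mirror that logic: orient each merged read so the leader
is at the 5' end, count approximate repeat occurrences, and cut out the
leader-proximal insert, discarding fragments of aberrant length
(shorter than 10 bp or longer than 45 bp).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

from .fileio import SeqRead, revcomp

logger = logging.getLogger(__name__)

#: Inclusive bounds on an extracted spacer length; fragments outside are excluded.
MIN_SPACER_LENGTH = 10
MAX_SPACER_LENGTH = 45


@dataclass
class CrisprArray:
    """A CRISPR array: leader, one repeat and the ordered spacer sequences.

    Spacer index 0 is the leader-proximal spacer, i.e. the most recently
    acquired one in a type I system.  ``baseline_repeat_count_in_amplicon``
    is the number of repeats a no-acquisition amplicon contains (three, for
    primers spanning leader to third spacer).
    """

    array_id: str
    leader: str
    repeat: str
    spacers: list[str]
    baseline_repeat_count_in_amplicon: int = 3

    def __post_init__(self) -> None:
        if not self.spacers:
            raise ValueError("a CRISPR array must contain at least one spacer")
        if len(self.repeat) < 15:
            raise ValueError("repeat sequences shorter than 15 bp are not supported")

    def baseline_amplicon(self) -> str:
        """The no-acquisition amplicon: leader followed by repeat+spacer units."""
        n = self.baseline_repeat_count_in_amplicon
        units = "".join(self.repeat + s for s in self.spacers[:n])
        return self.leader + units


@dataclass
class RepeatMatch:
    """One approximate repeat occurrence in an oriented read (0-based, half-open)."""

    start: int
    end: int
    mismatches: int


@dataclass
class ExtractedSpacer:
    """The candidate spacer cut from one read, with the filters applied."""

    read_id: str
    array_id: str
    sequence: str | None
    repeat_count: int
    status: str  # kept | too_short | too_long | not_expanded | ambiguous_orientation


def filter_reads(reads: Sequence[SeqRead], min_length: int = 300) -> list[SeqRead]:
    """Keep only reads strictly longer than ``min_length`` bases.

    A read of exactly ``min_length`` is discarded; amplicons at or below that
    size cannot carry an inserted spacer-repeat unit.
    """
    if not reads:
        logger.warning("filter_reads received no reads")
        return []
    kept = [r for r in reads if len(r.seq) > min_length]
    logger.info("filter_reads: kept %d of %d reads (min length %d, strict)",
                len(kept), len(reads), min_length)
    return kept


def orient_read(
    read: str,
    array: CrisprArray,
    probe_length: int = 20,
    max_probe_distance: int = 4,
) -> tuple[str, str] | None:
    """Orient a read so the leader-derived primer region sits at the 5' end.

    The 3'-most ``probe_length`` bases of the leader are searched on both
    strands with an infix edit-distance alignment.  The strand with the
    smaller distance wins; a tie, or no hit within ``max_probe_distance``,
    is reported as ambiguous (``None``).

    Returns ``(oriented_sequence, strand)`` with strand ``"forward"`` or
    ``"reverse"``, or ``None`` when the orientation is ambiguous.
    """
    probe = array.leader[-probe_length:]
    rc = revcomp(read)
    d_fwd = edlib.align(probe, read, mode="HW", task="distance")["editDistance"]
    d_rev = edlib.align(probe, rc, mode="HW", task="distance")["editDistance"]
    best = min(d_fwd, d_rev)
    if best > max_probe_distance or d_fwd == d_rev:
        return None
    return (read, "forward") if d_fwd < d_rev else (rc, "reverse")


def find_repeat_occurrences(
    oriented_read: str, repeat: str, max_mismatches: int = 2
) -> list[RepeatMatch]:
    """All non-overlapping repeat occurrences with at most ``max_mismatches`` substitutions.

    Occurrences are selected greedily left to right (leftmost start wins on
    overlap), which matches the linear repeat-spacer structure of an amplicon
    and makes the result deterministic.  Indels are not modelled.
    """
    rlen = len(repeat)
    if rlen > len(oriented_read):
        return []
    read_arr = np.frombuffer(oriented_read.encode("ascii"), dtype=np.uint8)
    rep_arr = np.frombuffer(repeat.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(read_arr, rlen)
    mismatch_counts = (windows != rep_arr).sum(axis=1)
    candidates = np.flatnonzero(mismatch_counts <= max_mismatches)
    matches: list[RepeatMatch] = []
    cursor = 0
    for start in candidates:
        if start >= cursor:
            matches.append(RepeatMatch(int(start), int(start) + rlen, int(mismatch_counts[start])))
            cursor = int(start) + rlen
    return matches


def extract_leader_proximal_spacer(
    oriented_read: str, matches: Sequence[RepeatMatch], array: CrisprArray,
    read_id: str = "",
) -> ExtractedSpacer:
    """Cut the sequence between the two repeats closest to the leader end.

    Reads whose repeat count does not exceed the baseline carry no insert
    (``not_expanded``).  The extracted fragment is then length-filtered:
    shorter than 10 bp is ``too_short``, longer than 45 bp ``too_long``,
    otherwise ``kept``.
    """
    for prev, cur in zip(matches, matches[1:]):
        if cur.start < prev.end:
            raise ValueError("repeat matches overlap or are out of order")
    repeat_count = len(matches)
    if repeat_count <= array.baseline_repeat_count_in_amplicon:
        return ExtractedSpacer(read_id, array.array_id, None, repeat_count, "not_expanded")
    sequence = oriented_read[matches[0].end : matches[1].start]
    if len(sequence) < MIN_SPACER_LENGTH:
        status = "too_short"
    elif len(sequence) > MAX_SPACER_LENGTH:
        status = "too_long"
    else:
        status = "kept"
    return ExtractedSpacer(read_id, array.array_id, sequence, repeat_count, status)


def extract_spacers(
    reads: Sequence[SeqRead],
    array: CrisprArray,
    min_read_length: int = 300,
    max_repeat_mismatches: int = 2,
    probe_length: int = 20,
    max_probe_distance: int = 4,
) -> pd.DataFrame:
    """Run the full extraction pipeline on merged amplicon reads.

    Returns one row per read surviving the length filter with columns
    ``read_id, array_id, repeat_count, status, spacer``.
    """
    rows = []
    for read in filter_reads(reads, min_length=min_read_length):
        oriented = orient_read(read.seq, array, probe_length, max_probe_distance)
        if oriented is None:
            rows.append((read.id, array.array_id, 0, "ambiguous_orientation", None))
            continue
        seq, _strand = oriented
        matches = find_repeat_occurrences(seq, array.repeat, max_repeat_mismatches)
        extracted = extract_leader_proximal_spacer(seq, matches, array, read_id=read.id)
        rows.append((read.id, array.array_id, extracted.repeat_count,
                     extracted.status, extracted.sequence))
    return pd.DataFrame(
        rows, columns=["read_id", "array_id", "repeat_count", "status", "spacer"]
    )
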