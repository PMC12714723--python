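"""Read-depth profiles, elevated-coverage element calls and topology typing.

A replicating (pro)viral element shows up in shotgun data as a run of
windows whose depth is a multiple of the genome-wide baseline.  The
baseline is the *median* of window depths rather than the arithmetic mean:
a 20-fold-amplified element would otherwise inflate its own reference
point.  Candidate elements are maximal runs of consecutive windows at or
above a fold-enrichment threshold.

Topology is then typed from the reads themselves:

* circular evidence — reads whose 5' and 3' anchors place in back-to-front
  order on the reference (the read runs off the element end and continues
  at its start), the sequencing analogue of an outward-facing PCR;
* integration evidence — reads that span a host-element edge of the call
  contiguously.  An edge that coincides with a replicon end cannot be
  assessed and is reported as ``None``, not zero.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .fileio import SeqRead, revcomp

logger = logging.getLogger(__name__)

DEFAULT_SEED_K = 21
DEFAULT_MAX_MISMATCHES = 3

_MULTI = ("__multi__", -1)


@dataclass
class Alignment:
    """An ungapped read placement (0-based half-open, forward coordinates)."""

    read_id: str
    replicon: str
    start: int
    end: int
    strand: str
    n_mismatches: int = 0


@dataclass
class CoverageProfile:
    """Tiled window depths with fold enrichment over the genome median."""

    window_size: int
    windows: pd.DataFrame  # replicon, start, end, depth, enrichment
    robust_genome_mean: float
    replicon_lengths: dict[str, int]


@dataclass
class ElementCall:
    """A candidate mobile element with junction-read evidence."""

    replicon: str
    start: int
    end: int
    mean_enrichment: float
    n_circular_junction_reads: int | None = None
    n_integration_junction_reads: int | None = None
    topology: str = "undetermined"  # circular | integrated | both | undetermined


class ReadMapper:
    """Unique-seed ungapped mapper for synthetic/short shotgun reads.

    Each read is anchored by exact k-mer seeds (k = 21 by default) taken
    from its ends and middle on both strands.  A read whose seeds imply a
    single placement is verified by an ungapped comparison allowing a few
    substitutions; reads whose seeds are repeated in the reference or imply
    conflicting placements are dropped as multi-mapping.
    """

    def __init__(self, replicons: Mapping[str, str], k: int = DEFAULT_SEED_K):
        if not replicons:
            raise ValueError("no reference replicons supplied")
        self.replicons = {name: seq.upper() for name, seq in replicons.items()}
        self.k = k
        self.ref_bytes = {
            name: np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            for name, seq in self.replicons.items()
        }
        self.index: dict[str, tuple[str, int]] = {}
        for name, seq in self.replicons.items():
            for i in range(len(seq) - k + 1):
                word = seq[i:i + k]
                if word in self.index:
                    self.index[word] = _MULTI
                else:
                    self.index[word] = (name, i)

    def place(self, seq: str, max_mismatches: int = DEFAULT_MAX_MISMATCHES
              ) -> tuple[str, Alignment | None]:
        """Place one read; returns (outcome, alignment).

        Outcomes: ``mapped``, ``multi`` (repeated seed or conflicting
        placements), ``unplaced`` (no seed or failed verification).
        """
        k = self.k
        n = len(seq)
        if n < k:
            return "unplaced", None
        placements: set[tuple[str, int, str]] = set()
        saw_multi = False
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            for offset in (0, (n - k) // 2, n - k):
                hit = self.index.get(oriented[offset:offset + k])
                if hit is None:
                    continue
                if hit == _MULTI:
                    saw_multi = True
                    continue
                placements.add((hit[0], hit[1] - offset, strand))
        if saw_multi or len(placements) > 1:
            return "multi", None
        if not placements:
            return "unplaced", None
        replicon, start, strand = placements.pop()
        ref = self.ref_bytes[replicon]
        if start < 0 or start + n > len(ref):
            return "unplaced", None
        oriented = seq if strand == "+" else revcomp(seq)
        read_arr = np.frombuffer(oriented.encode("ascii"), dtype=np.uint8)
        mismatches = int((ref[start:start + n] != read_arr).sum())
        if mismatches > max_mismatches:
            return "unplaced", None
        return "mapped", Alignment("", replicon, start, start + n, strand, mismatches)


def map_reads(
    reads: Sequence[SeqRead],
    replicons: Mapping[str, str],
    k: int = DEFAULT_SEED_K,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    mapper: ReadMapper | None = None,
) -> list[Alignment]:
    """Map reads with the unique-seed ungapped strategy; multi-mappers are dropped."""
    mapper = mapper or ReadMapper(replicons, k)
    alignments = []
    n_multi = n_unplaced = 0
    for read in reads:
        outcome, aln = mapper.place(read.seq, max_mismatches)
        if outcome == "mapped":
            aln.read_id = read.id
            alignments.append(aln)
        elif outcome == "multi":
            n_multi += 1
        else:
            n_unplaced += 1
    logger.info("map_reads: %d mapped, %d multi-mapping dropped, %d unplaced",
                len(alignments), n_multi, n_unplaced)
    return alignments


def read_alignments_sam(path: str) -> list[Alignment]:
    """Load primary alignments from a SAM/BAM file as :class:`Alignment` records."""
    alignments = []
    with pysam.AlignmentFile(path, check_sq=False) as handle:
        for rec in handle:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            alignments.append(Alignment(
                rec.query_name, rec.reference_name,
                rec.reference_start, rec.reference_end,
                "-" if rec.is_reverse else "+",
            ))
    return alignments


def write_alignments_sam(
    alignments: Iterable[Alignment],
    replicon_lengths: Mapping[str, int],
    path: str,
) -> None:
    """Write ungapped alignments as a plain-text SAM file."""
    names = list(replicon_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": int(replicon_lengths[n])} for n in names],
    }
    with pysam.AlignmentFile(path, "w", header=header) as handle:
        for aln in alignments:
            rec = pysam.AlignedSegment(handle.header)
            rec.query_name = aln.read_id
            rec.reference_id = names.index(aln.replicon)
            rec.reference_start = aln.start
            rec.mapping_quality = 60
            rec.cigarstring = f"{aln.end - aln.start}M"
            rec.flag = 16 if aln.strand == "-" else 0
            handle.write(rec)


def depth_profile(
    alignments: Sequence[Alignment],
    replicon_lengths: Mapping[str, int],
    window_size: int = 500,
) -> CoverageProfile:
    """Per-window mean depth and enrichment over the genome-median baseline."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    per_replicon: dict[str, np.ndarray] = {}
    for name, length in replicon_lengths.items():
        diff = np.zeros(length + 1, dtype=np.int64)
        per_replicon[name] = diff
    for aln in alignments:
        diff = per_replicon.get(aln.replicon)
        if diff is None:
            raise ValueError(f"alignment references unknown replicon {aln.replicon!r}")
        diff[aln.start] += 1
        diff[min(aln.end, len(diff) - 1)] -= 1
    rows = []
    for name, length in replicon_lengths.items():
        depth = np.cumsum(per_replicon[name][:length])
        for w_start in range(0, length, window_size):
            w_end = min(w_start + window_size, length)
            rows.append((name, w_start, w_end, float(depth[w_start:w_end].mean())))
    windows = pd.DataFrame(rows, columns=["replicon", "start", "end", "depth"])
    robust = float(np.median(windows["depth"])) if len(windows) else 0.0
    if robust > 0:
        # second pass: drop clearly amplified windows so a multi-copy element
        # does not inflate its own baseline
        baseline = windows["depth"][windows["depth"] < 2.0 * robust]
        if len(baseline):
            robust = float(np.median(baseline))
    windows["enrichment"] = windows["depth"] / robust if robust > 0 else np.nan
    return CoverageProfile(window_size, windows, robust, dict(replicon_lengths))


def call_elements(
    profile: CoverageProfile,
    threshold: float = 2.5,
    min_windows: int = 2,
) -> list[ElementCall]:
    """Merge runs of >= ``min_windows`` consecutive enriched windows into calls."""
    calls: list[ElementCall] = []
    for replicon, group in profile.windows.groupby("replicon", sort=False):
        run: list[pd.Series] = []
        for _, row in group.iterrows():
            if row["enrichment"] >= threshold:
                run.append(row)
            else:
                if len(run) >= min_windows:
                    calls.append(_call_from_run(replicon, run))
                run = []
        if len(run) >= min_windows:
            calls.append(_call_from_run(replicon, run))
    return calls


def _call_from_run(replicon: str, run: list[pd.Series]) -> ElementCall:
    # the first and last window of a run straddle the element edges and are
    # diluted by flanking baseline coverage; drop them from the fold estimate
    # whenever enough interior windows remain
    values = [r["enrichment"] for r in run]
    interior = values[1:-1] if len(values) >= 4 else values
    return ElementCall(
        replicon=replicon,
        start=int(run[0]["start"]),
        end=int(run[-1]["end"]),
        mean_enrichment=float(np.mean(interior)),
    )


def junction_typing(
    reads: Sequence[SeqRead],
    call: ElementCall,
    replicons: Mapping[str, str],
    evidence_threshold: int = 3,
    k: int = DEFAULT_SEED_K,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    edge_margin: int = 10,
    min_enrichment: float = 2.5,
    mapper: ReadMapper | None = None,
) -> ElementCall:
    """Type an element call as circular, integrated, both or undetermined.

    Circular evidence counts reads without a contiguous placement whose
    5' anchor k-mer places *after* their 3' anchor k-mer on the call's
    replicon (back-to-front geometry, i.e. the read crosses the element
    end-to-start junction).  Integration evidence counts contiguously
    placed reads spanning a call edge by at least ``edge_margin`` bases on
    each side; an edge at a replicon boundary is not assessable, and when
    neither edge is assessable the integration count is ``None``.

    Contiguous coverage across an interval edge is only evidence of
    integration when the interval is an established elevated-copy element
    (in a reference that carries the element embedded, every baseline
    region trivially has edge-spanning reads), so integration evidence is
    counted only for calls at or above ``min_enrichment``.
    """
    mapper = mapper or ReadMapper(replicons, k)
    seq_len = len(mapper.replicons[call.replicon])
    enriched = call.mean_enrichment >= min_enrichment
    left_ok = enriched and call.start >= edge_margin
    right_ok = enriched and call.end + edge_margin <= seq_len
    region_lo = call.start - max((len(r.seq) for r in reads), default=0)
    region_hi = call.end + max((len(r.seq) for r in reads), default=0)

    n_circular = 0
    n_integration = 0
    for read in reads:
        outcome, aln = mapper.place(read.seq, max_mismatches)
        if outcome == "mapped":
            if aln.replicon != call.replicon:
                continue
            spans_left = left_ok and aln.start <= call.start - edge_margin \
                and aln.end >= call.start + edge_margin
            spans_right = right_ok and aln.start <= call.end - edge_margin \
                and aln.end >= call.end + edge_margin
            if spans_left or spans_right:
                n_integration += 1
            continue
        # a junction read's end anchors imply conflicting placements, so it
        # surfaces as "multi" or "unplaced"; the split check sorts it out
        n_circular += _is_backward_split(read.seq, mapper, call, region_lo, region_hi)

    integration: int | None = n_integration if (left_ok or right_ok) else None
    circular_hit = n_circular >= evidence_threshold
    integration_hit = integration is not None and integration >= evidence_threshold
    if circular_hit and integration_hit:
        topology = "both"
    elif circular_hit:
        topology = "circular"
    elif integration_hit:
        topology = "integrated"
    else:
        topology = "undetermined"
    return ElementCall(
        call.replicon, call.start, call.end, call.mean_enrichment,
        n_circular_junction_reads=n_circular,
        n_integration_junction_reads=integration,
        topology=topology,
    )


def _is_backward_split(
    seq: str, mapper: ReadMapper, call: ElementCall, region_lo: int, region_hi: int
) -> bool:
    """Does this unplaced read anchor back-to-front across the call region?"""
    k = mapper.k
    if len(seq) < 2 * k:
        return False
    for oriented in (seq, revcomp(seq)):
        head = mapper.index.get(oriented[:k])
        tail = mapper.index.get(oriented[-k:])
        if (head is None or tail is None or head == _MULTI or tail == _MULTI):
            continue
        if head[0] != call.replicon or tail[0] != call.replicon:
            continue
        head_pos, tail_pos = head[1], tail[1]
        if tail_pos < head_pos \
                and region_lo <= tail_pos and head_pos + k <= region_hi:
            return True
    return False
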