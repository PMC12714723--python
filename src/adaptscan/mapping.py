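"""Map new spacers to their genomic source (protospacer) and read off the PAM.

The search follows the conventional short-nucleotide-query recipe: exact
word seeds (word size 7) anchor candidate diagonals on both strands, each
diagonal is refined with a gapped local alignment (match +1, mismatch -3,
gap open -5, gap extend -2 per base), and hits scoring within 90% of the
best raw score are retained.  Candidates are then filtered with four strict
criteria, all inequalities strict:

* percent identity > 95,
* number of mismatches < 4,
* alignment length / query length > 0.9,
* |query alignment span - query length| < 3.

Among passing hits the unique highest raw score wins; an exact score tie
makes the spacer ambiguous and excludes it from the location and PAM
summaries; no passing hit leaves it unmapped.  The PAM is the trinucleotide
immediately 5' of the protospacer, read on the protospacer strand.

Coordinates are 0-based half-open on the forward reference throughout;
minus-strand hits keep start < end.
"""
from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align

from .fileio import revcomp

logger = logging.getLogger(__name__)

DEFAULT_WORD_SIZE = 7
MATCH_SCORE = 1
MISMATCH_SCORE = -3
GAP_OPEN = -5     # charged once per gap
GAP_EXTEND = -2   # charged per gap base, including the first
SCORE_RETENTION = 0.9

MIN_IDENTITY = 95.0       # percent, strict
MAX_MISMATCHES = 4        # strict upper bound (mismatches < 4)
MIN_LENGTH_RATIO = 0.9    # alignment length / query length, strict
MAX_LENGTH_DIFF = 3       # |query span - query length|, strict


@dataclass
class ProtospacerHit:
    """One candidate or resolved protospacer alignment."""

    spacer_id: str
    replicon: str
    start: int
    end: int
    strand: str  # "+" or "-"
    alignment_length: int
    query_span: int
    n_mismatches: int
    n_gaps: int
    percent_identity: float
    raw_score: float
    status: str = "candidate"  # candidate | best | filtered_out | ambiguous_tie
    pam: str | None = None


@dataclass
class PamSummary:
    """PAM trinucleotide counts with the expectation under reference composition."""

    counts: dict[str, int]
    top_motif: str | None
    top_fraction: float
    background: dict[str, float] = field(default_factory=dict)


@dataclass
class LocusDistribution:
    """Binned protospacer counts and the most-targeted locus."""

    bin_size: int
    counts: pd.DataFrame  # replicon, bin_start, bin_end, count
    top_locus: tuple[str, tuple[int, int], float] | None


class ReferenceIndex:
    """Exact word index over a set of replicons (forward strand)."""

    def __init__(self, replicons: Mapping[str, str], word_size: int = DEFAULT_WORD_SIZE):
        if not replicons or all(len(s) == 0 for s in replicons.values()):
            raise ValueError("empty reference")
        self.replicons = {k: v.upper() for k, v in replicons.items()}
        self.word_size = word_size
        self.words: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in self.replicons.items():
            for i in range(len(seq) - word_size + 1):
                self.words[seq[i:i + word_size]].append((name, i))


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    # a gap of length g costs |GAP_OPEN| + g * |GAP_EXTEND|
    aligner.open_gap_score = GAP_OPEN + GAP_EXTEND
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_ALIGNER = _make_aligner()


def _hit_from_alignment(
    alignment, window: str, query: str, window_offset: int,
    spacer_id: str, replicon: str, strand: str,
) -> ProtospacerHit | None:
    target_blocks, query_blocks = alignment.aligned
    if len(target_blocks) == 0:
        return None
    matches = 0
    aligned_cols = 0
    for (ts, te), (qs, qe) in zip(target_blocks, query_blocks):
        aligned_cols += te - ts
        matches += sum(1 for x, y in zip(window[ts:te], query[qs:qe]) if x == y)
    t_span = int(target_blocks[-1][1] - target_blocks[0][0])
    q_span = int(query_blocks[-1][1] - query_blocks[0][0])
    n_gaps = (t_span - aligned_cols) + (q_span - aligned_cols)
    alignment_length = aligned_cols + n_gaps
    identity = 100.0 * matches / alignment_length if alignment_length else 0.0
    return ProtospacerHit(
        spacer_id=spacer_id,
        replicon=replicon,
        start=window_offset + int(target_blocks[0][0]),
        end=window_offset + int(target_blocks[-1][1]),
        strand=strand,
        alignment_length=alignment_length,
        query_span=q_span,
        n_mismatches=aligned_cols - matches,
        n_gaps=n_gaps,
        percent_identity=identity,
        raw_score=float(alignment.score),
    )


def _diagonal_screen(seq: str, diagonal: int, query: str) -> int:
    """Best ungapped segment score of the query on one diagonal (Kadane)."""
    lo = max(0, diagonal)
    hi = min(len(seq), diagonal + len(query))
    if hi - lo < 1:
        return 0
    q = query[lo - diagonal:hi - diagonal]
    best = cur = 0
    for ref_base, q_base in zip(seq[lo:hi], q):
        cur += MATCH_SCORE if ref_base == q_base else MISMATCH_SCORE
        if cur < 0:
            cur = 0
        elif cur > best:
            best = cur
    return best


def align_spacer(
    spacer: str,
    reference: Mapping[str, str] | ReferenceIndex,
    spacer_id: str = "spacer",
    word_size: int = DEFAULT_WORD_SIZE,
    window_pad: int = 8,
) -> list[ProtospacerHit]:
    """All seeded local alignments of a spacer, both strands, unfiltered.

    Hits within :data:`SCORE_RETENTION` of the best raw score are returned,
    sorted by descending score with deterministic coordinate tie-breaking.
    """
    index = reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(reference, word_size)
    spacer = spacer.upper()
    w = index.word_size
    hits: dict[tuple[str, int, int, str], ProtospacerHit] = {}
    per_strand: dict[str, list[tuple[int, str, int]]] = {}
    best_ungapped = 0
    for strand in ("+", "-"):
        query = spacer if strand == "+" else revcomp(spacer)
        diagonals: set[tuple[str, int]] = set()
        for offset in range(len(query) - w + 1):
            for replicon, pos in index.words.get(query[offset:offset + w], ()):
                diagonals.add((replicon, pos - offset))
        scored = [(_diagonal_screen(index.replicons[rep], diag, query), rep, diag)
                  for rep, diag in sorted(diagonals)]
        per_strand[strand] = scored
        if scored:
            best_ungapped = max(best_ungapped, max(s for s, _, _ in scored))
    # a diagonal whose gapped alignment could compete carries a contiguous
    # ungapped segment well above the random background; prune the rest
    floor = max(w + 3, int(0.5 * best_ungapped))
    for strand in ("+", "-"):
        query = spacer if strand == "+" else revcomp(spacer)
        for screen_score, replicon, diagonal in per_strand[strand]:
            if screen_score < floor:
                continue
            seq = index.replicons[replicon]
            w_start = max(0, diagonal - window_pad)
            w_end = min(len(seq), diagonal + len(query) + window_pad)
            window = seq[w_start:w_end]
            if len(window) < w:
                continue
            alignments = _ALIGNER.align(window, query)
            if not alignments or alignments.score <= 0:
                continue
            hit = _hit_from_alignment(
                alignments[0], window, query, w_start, spacer_id, replicon, strand
            )
            if hit is None:
                continue
            key = (hit.replicon, hit.start, hit.end, hit.strand)
            if key not in hits or hit.raw_score > hits[key].raw_score:
                hits[key] = hit
    if not hits:
        return []
    best = max(h.raw_score for h in hits.values())
    kept = [h for h in hits.values() if h.raw_score >= SCORE_RETENTION * best]
    kept.sort(key=lambda h: (-h.raw_score, h.replicon, h.start, h.strand))
    return kept


def filter_hits(hits: Iterable[ProtospacerHit], spacer: str) -> list[ProtospacerHit]:
    """Apply the four strict filters, setting status candidate/filtered_out."""
    qlen = len(spacer)
    out = []
    for hit in hits:
        passes = (
            hit.percent_identity > MIN_IDENTITY
            and hit.n_mismatches < MAX_MISMATCHES
            and hit.alignment_length / qlen > MIN_LENGTH_RATIO
            and abs(hit.query_span - qlen) < MAX_LENGTH_DIFF
        )
        hit.status = "candidate" if passes else "filtered_out"
        out.append(hit)
    return out


def resolve_best(hits: Sequence[ProtospacerHit]) -> tuple[str, ProtospacerHit | None]:
    """Resolve multi-mapping by raw score.

    Returns ``("best", hit)`` for a unique maximum, ``("ambiguous_tie", None)``
    when two or more passing hits share the maximum score (those hits are
    marked and excluded from location/PAM summaries), and
    ``("unmapped", None)`` when no hit passed the filters.
    """
    passing = [h for h in hits if h.status == "candidate"]
    if not passing:
        return "unmapped", None
    top = max(h.raw_score for h in passing)
    winners = [h for h in passing if h.raw_score == top]
    if len(winners) > 1:
        for h in winners:
            h.status = "ambiguous_tie"
        return "ambiguous_tie", None
    winners[0].status = "best"
    return "best", winners[0]


def extract_pam(
    hit: ProtospacerHit,
    replicons: Mapping[str, str],
    pam_length: int = 3,
    side: str = "5prime",
) -> str | None:
    """The PAM adjacent to a best hit, read on the protospacer strand.

    By default the ``pam_length`` bases immediately 5' of the protospacer
    start (type I convention); ``side="3prime"`` reads the other flank.
    Returns ``None`` when the window runs off the replicon end.
    """
    seq = replicons[hit.replicon]
    if hit.start < 0 or hit.end > len(seq):
        raise ValueError("hit coordinates fall outside the replicon")
    five_prime = side == "5prime"
    upstream = five_prime == (hit.strand == "+")
    if upstream:
        if hit.start - pam_length < 0:
            return None
        window = seq[hit.start - pam_length:hit.start]
    else:
        if hit.end + pam_length > len(seq):
            return None
        window = seq[hit.end:hit.end + pam_length]
    return window if hit.strand == "+" else revcomp(window)


def map_new_spacers(
    spacers: pd.DataFrame,
    replicons: Mapping[str, str],
    word_size: int = DEFAULT_WORD_SIZE,
    pam_length: int = 3,
    pam_side: str = "5prime",
) -> pd.DataFrame:
    """Align, filter and resolve every new spacer; annotate best hits with PAM.

    ``spacers`` needs columns ``read_id`` and ``sequence`` (the frame
    produced by the classifier, restricted to label ``new``, fits directly).
    Returns one row per spacer with the resolved status and, for best hits,
    the full alignment fields and PAM.
    """
    index = ReferenceIndex(replicons, word_size)
    rows = []
    for spacer_id, seq in zip(spacers["read_id"], spacers["sequence"]):
        hits = align_spacer(seq, index, spacer_id=spacer_id)
        hits = filter_hits(hits, seq)
        status, best = resolve_best(hits)
        if best is None:
            rows.append((spacer_id, seq, status, None, None, None, None,
                         None, None, None, None))
        else:
            pam = extract_pam(best, index.replicons, pam_length, pam_side)
            best.pam = pam
            rows.append((spacer_id, seq, status, best.replicon, best.start,
                         best.end, best.strand, best.percent_identity,
                         best.n_mismatches, best.raw_score, pam))
    return pd.DataFrame(
        rows,
        columns=["read_id", "sequence", "status", "replicon", "start", "end",
                 "strand", "percent_identity", "n_mismatches", "raw_score", "pam"],
    )


def _trinucleotide_background(replicons: Mapping[str, str], k: int) -> dict[str, float]:
    counts: Counter[str] = Counter()
    for seq in replicons.values():
        for strand_seq in (seq, revcomp(seq)):
            for i in range(len(strand_seq) - k + 1):
                counts[strand_seq[i:i + k]] += 1
    total = sum(counts.values())
    return {motif: c / total for motif, c in sorted(counts.items())}


def pam_summary(
    best_hits: pd.DataFrame,
    replicons: Mapping[str, str] | None = None,
    pam_length: int = 3,
) -> PamSummary:
    """Tally PAMs over best hits; optionally add the composition-expected background."""
    mapped = best_hits[(best_hits["status"] == "best") & best_hits["pam"].notna()]
    counts = dict(Counter(mapped["pam"]))
    if not counts:
        logger.warning("pam_summary: no best hits with a defined PAM")
        return PamSummary({}, None, 0.0, {})
    top_motif, top_count = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    background = _trinucleotide_background(replicons, pam_length) if replicons else {}
    return PamSummary(counts, top_motif, top_count / sum(counts.values()), background)


def locus_distribution(
    best_hits: pd.DataFrame,
    replicon_lengths: Mapping[str, int],
    bin_size: int = 1_000,
) -> LocusDistribution:
    """Bin best protospacer hits along each replicon and report the top locus."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    mapped = best_hits[best_hits["status"] == "best"]
    rows = []
    for replicon, length in replicon_lengths.items():
        n_bins = (length + bin_size - 1) // bin_size
        in_rep = mapped[mapped["replicon"] == replicon]
        binned = (in_rep["start"].astype(int) // bin_size).value_counts()
        for b in range(n_bins):
            rows.append((replicon, b * bin_size, min((b + 1) * bin_size, length),
                         int(binned.get(b, 0))))
    counts = pd.DataFrame(rows, columns=["replicon", "bin_start", "bin_end", "count"])
    total = counts["count"].sum()
    if total == 0:
        logger.warning("locus_distribution: no best hits")
        return LocusDistribution(bin_size, counts, None)
    top = counts.loc[counts["count"].idxmax()]
    top_locus = (top["replicon"], (int(top["bin_start"]), int(top["bin_end"])),
                 top["count"] / total)
    return LocusDistribution(bin_size, counts, top_locus)
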