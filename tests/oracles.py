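"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately share no code with the implementation: the mapping
oracle scans every offset on both strands with an ungapped local-alignment
(maximum-scoring segment) computation, and the distance oracle is a plain
dynamic-programming edit distance.
"""
from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def dp_edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance, plain O(nm) DP."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, start=1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return prev[-1]


def oracle_spacer_distance(query: str, target: str) -> int:
    """Min over strands; Hamming for equal lengths, DP edit otherwise."""
    best = None
    for cand in (target, rc(target)):
        if len(query) == len(cand):
            d = sum(1 for x, y in zip(query, cand) if x != y)
        else:
            d = dp_edit_distance(query, cand)
        best = d if best is None else min(best, d)
    return best


def oracle_classify(query: str, arrays, max_mismatches: int = 10):
    """Exhaustive all-pairs classification with (array, index) tie-breaking."""
    best = None
    for a_pos, array in enumerate(arrays):
        for s_idx, spacer in enumerate(array.spacers):
            key = (oracle_spacer_distance(query, spacer), a_pos, s_idx)
            if best is None or key < best:
                best = key
    d, a_pos, s_idx = best
    if d <= max_mismatches:
        return "duplicate", arrays[a_pos].array_id, s_idx, d
    return "new", None, None, d


def _best_segment(scores: list[int]) -> tuple[int, int, int]:
    """Maximum-scoring contiguous segment (Kadane), leftmost on ties."""
    best, best_lo, best_hi = 0, 0, 0
    cur, cur_lo = 0, 0
    for i, s in enumerate(scores):
        if cur <= 0:
            cur, cur_lo = s, i
        else:
            cur += s
        if cur > best:
            best, best_lo, best_hi = cur, cur_lo, i + 1
    return best, best_lo, best_hi


def oracle_map(spacer: str, replicons: dict[str, str], score_floor: int = 18):
    """Every-offset, both-strand ungapped local alignment and strict filtering.

    Mirrors the published filter criteria (identity > 95, mismatches < 4,
    length ratio > 0.9, length difference < 3, strict) and highest-raw-score
    resolution with tie exclusion.  Returns ``(status, locus_dict_or_None)``.
    ``score_floor`` only prunes offsets that could never pass the filters
    (a passing ~34-45 nt hit scores far above it).
    """
    L = len(spacer)
    candidates = []
    for rep, seq in replicons.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        if len(arr) < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)
        for strand, q in (("+", spacer), ("-", rc(spacer))):
            qa = np.frombuffer(q.encode("ascii"), dtype=np.uint8)
            eq = windows == qa
            sc = np.where(eq, 1, -3).astype(np.int32)
            prefix = np.zeros((sc.shape[0], L + 1), dtype=np.int32)
            np.cumsum(sc, axis=1, out=prefix[:, 1:])
            run_min = np.minimum.accumulate(prefix[:, :-1], axis=1)
            best_per_offset = (prefix[:, 1:] - run_min).max(axis=1)
            for off in np.flatnonzero(best_per_offset >= score_floor):
                score, lo, hi = _best_segment(sc[off].tolist())
                matches = int(eq[off, lo:hi].sum())
                alen = hi - lo
                mism = alen - matches
                identity = 100.0 * matches / alen
                passes = (identity > 95.0 and mism < 4
                          and alen / L > 0.9 and abs(alen - L) < 3)
                candidates.append(dict(
                    replicon=rep, start=int(off + lo), end=int(off + hi),
                    strand=strand, identity=identity, mismatches=mism,
                    score=score, passes=passes,
                ))
    passing = [c for c in candidates if c["passes"]]
    if not passing:
        return "unmapped", None
    top = max(c["score"] for c in passing)
    winners = [c for c in passing if c["score"] == top]
    loci = {(c["replicon"], c["start"], c["end"], c["strand"]) for c in winners}
    if len(loci) > 1:
        return "ambiguous_tie", None
    return "best", winners[0]
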