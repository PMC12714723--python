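"""Brute-force every-offset protospacer-mapping oracle used by acceptance.py.

Independent of the package's seeded aligner: scans every offset on both
strands with an ungapped maximum-scoring-segment computation and applies
the same published filter criteria.
"""
from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def _rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _best_segment(scores: list[int]) -> tuple[int, int, int]:
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
    L = len(spacer)
    candidates = []
    for rep, seq in replicons.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        if len(arr) < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)
        for strand, q in (("+", spacer), ("-", _rc(spacer))):
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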