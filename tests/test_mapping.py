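"""Protospacer alignment, strict filtering, best-hit resolution and PAM."""
import numpy as np
import pytest

from adaptscan.fileio import revcomp
from adaptscan.mapping import (
    ProtospacerHit,
    ReferenceIndex,
    align_spacer,
    extract_pam,
    filter_hits,
    locus_distribution,
    map_new_spacers,
    pam_summary,
    resolve_best,
)
from adaptscan.simulate import random_sequence


@pytest.fixture(scope="module")
def planted_ref():
    rng = np.random.default_rng(4_242)
    ref = random_sequence(rng, 20_000)
    spacer = random_sequence(rng, 37)
    pos = 9_000
    ref = ref[:pos] + spacer + ref[pos + 37:]
    return {"chrom": ref}, spacer, pos


def _substitute(seq, positions):
    table = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = table[out[p]]
    return "".join(out)


class TestAlignSpacer:
    def test_perfect_match_full_score(self, planted_ref):
        ref, spacer, pos = planted_ref
        hits = align_spacer(spacer, ref)
        assert hits[0].start == pos and hits[0].end == pos + 37
        assert hits[0].strand == "+"
        assert hits[0].percent_identity == 100.0
        assert hits[0].n_mismatches == 0
        assert hits[0].raw_score == 37

    def test_one_internal_substitution_passes_identity(self, planted_ref):
        ref, spacer, _ = planted_ref
        query = _substitute(spacer, [18])
        hit = align_spacer(query, ref)[0]
        assert hit.n_mismatches == 1
        assert hit.percent_identity == pytest.approx(100 * 36 / 37)
        assert hit.percent_identity > 95

    def test_two_internal_substitutions_fail_identity_despite_mismatch_rule(
            self, planted_ref):
        """For ~37-mers the >95% identity filter dominates the mismatches<4 rule."""
        ref, spacer, _ = planted_ref
        query = _substitute(spacer, [12, 25])
        hits = filter_hits(align_spacer(query, ref), query)
        full = [h for h in hits if h.n_mismatches == 2]
        assert full and full[0].percent_identity == pytest.approx(100 * 35 / 37)
        assert full[0].percent_identity < 95
        status, _ = resolve_best(hits)
        assert status == "unmapped"

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            ReferenceIndex({})


class TestFilterArithmetic:
    def _hit(self, alignment_length, query_span, mismatches=0):
        matches = alignment_length - mismatches
        return ProtospacerHit("s", "chrom", 0, alignment_length, "+",
                              alignment_length, query_span, mismatches, 0,
                              100.0 * matches / alignment_length, float(matches))

    def test_alignment_length_ratio_boundary(self):
        spacer = "A" * 37
        short = self._hit(33, 33)   # 33/37 = 0.892 fails ratio
        ok = self._hit(35, 35)      # 0.946 passes ratio, |35-37| = 2 < 3 passes
        out = filter_hits([short, ok], spacer)
        assert out[0].status == "filtered_out"
        assert out[1].status == "candidate"

    def test_perfect_full_length_hit_passes_all(self):
        out = filter_hits([self._hit(37, 37)], "A" * 37)
        assert out[0].status == "candidate"


class TestResolveBest:
    def test_single_passing_hit_is_best(self, planted_ref):
        ref, spacer, pos = planted_ref
        hits = filter_hits(align_spacer(spacer, ref), spacer)
        status, best = resolve_best(hits)
        assert status == "best" and best.start == pos

    def test_duplicated_locus_is_ambiguous(self):
        rng = np.random.default_rng(7)
        spacer = random_sequence(rng, 37)
        filler = random_sequence(rng, 5_000)
        ref = {"chrom": filler + spacer + random_sequence(rng, 3_000) + spacer + filler}
        hits = filter_hits(align_spacer(spacer, ref), spacer)
        status, best = resolve_best(hits)
        assert status == "ambiguous_tie" and best is None

    def test_higher_score_locus_preserved(self):
        rng = np.random.default_rng(8)
        spacer = random_sequence(rng, 37)
        degraded = _substitute(spacer, [10, 20])  # score 35 - 6 - ... < 37
        ref = {"chrom": random_sequence(rng, 2_000) + spacer
               + random_sequence(rng, 2_000) + degraded
               + random_sequence(rng, 2_000)}
        hits = align_spacer(spacer, ref)
        scores = sorted({h.raw_score for h in hits}, reverse=True)
        assert scores[0] == 37
        status, best = resolve_best(filter_hits(hits, spacer))
        assert status == "best"
        assert best.start == 2_000 and best.raw_score == 37


class TestPam:
    def test_planted_upstream_pam_on_plus_strand(self):
        rng = np.random.default_rng(9)
        spacer = random_sequence(rng, 37)
        ref = {"chrom": random_sequence(rng, 1_000) + "TTC" + spacer
               + random_sequence(rng, 1_000)}
        hit = filter_hits(align_spacer(spacer, ref), spacer)
        _, best = resolve_best(hit)
        assert extract_pam(best, ref) == "TTC"

    def test_minus_strand_protospacer_reads_pam_from_downstream_flank(self):
        # protospacer on the minus strand: its 5'-adjacent TTC appears as
        # GAA immediately downstream on the forward reference
        rng = np.random.default_rng(9)
        spacer = random_sequence(rng, 37)
        ref = {"chrom": random_sequence(rng, 1_000) + revcomp(spacer) + "GAA"
               + random_sequence(rng, 1_000)}
        _, best = resolve_best(filter_hits(align_spacer(spacer, ref), spacer))
        assert best.strand == "-"
        assert extract_pam(best, ref) == "TTC"

    def test_window_off_replicon_end_gives_none(self):
        rng = np.random.default_rng(10)
        spacer = random_sequence(rng, 37)
        ref = {"chrom": "T" + spacer + random_sequence(rng, 500)}
        _, best = resolve_best(filter_hits(align_spacer(spacer, ref), spacer))
        assert best.start == 1
        assert extract_pam(best, ref) is None

    def test_out_of_bounds_hit_rejected(self):
        hit = ProtospacerHit("s", "chrom", 100, 500, "+", 37, 37, 0, 0, 100.0, 37.0)
        with pytest.raises(ValueError):
            extract_pam(hit, {"chrom": "ACGT" * 50})


class TestReverseComplementInvariance:
    def test_rc_query_maps_to_same_locus_with_flipped_strand(self):
        # flank the planted protospacer with TTC on both strands so the PAM
        # read-out is strand symmetric by construction
        rng = np.random.default_rng(12)
        spacer = random_sequence(rng, 37)
        ref = {"chrom": random_sequence(rng, 1_000) + "TTC" + spacer + "GAA"
               + random_sequence(rng, 1_000)}
        _, fwd = resolve_best(filter_hits(align_spacer(spacer, ref), spacer))
        _, rev = resolve_best(filter_hits(align_spacer(revcomp(spacer), ref),
                                          revcomp(spacer)))
        assert (fwd.start, fwd.end) == (rev.start, rev.end)
        assert {fwd.strand, rev.strand} == {"+", "-"}
        assert extract_pam(fwd, ref) == extract_pam(rev, ref) == "TTC"


@pytest.fixture(scope="module")
def mapped():
    import pandas as pd
    rng = np.random.default_rng(11)
    ref = random_sequence(rng, 30_000)
    spacers, rows = [], []
    for i in range(20):
        pos = 1_000 + i * 1_200
        spacer = random_sequence(rng, 37)
        ref = ref[:pos - 3] + "TTC" + spacer + ref[pos + 37:]
        rows.append((f"s{i}", spacer))
    replicons = {"chrom": ref}
    frame = pd.DataFrame(rows, columns=["read_id", "sequence"])
    return map_new_spacers(frame, replicons), replicons


class TestSummaries:
    def test_pam_counts_conserved(self, mapped):
        table, replicons = mapped
        summary = pam_summary(table, replicons)
        n_best = int((table["status"] == "best").sum())
        assert sum(summary.counts.values()) == n_best
        assert summary.top_motif == "TTC"
        assert summary.top_fraction == 1.0
        assert 0 < summary.background["TTC"] < 0.05

    def test_locus_bins_conserved(self, mapped):
        table, replicons = mapped
        dist = locus_distribution(table, {"chrom": 30_000}, bin_size=1_000)
        assert dist.counts["count"].sum() == int((table["status"] == "best").sum())

    def test_empty_hits_give_empty_summaries(self):
        import pandas as pd
        empty = pd.DataFrame(columns=["status", "pam", "replicon", "start"])
        assert pam_summary(empty).top_motif is None
        assert locus_distribution(empty, {"chrom": 5_000}).top_locus is None
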