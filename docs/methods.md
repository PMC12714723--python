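# Methods

## Scope and model

`adaptscan` analyses two read-outs of virus–host interaction in CRISPR-
carrying archaea: repeat–spacer amplicons from a spacer-acquisition assay,
and whole-genome shotgun coverage of a host carrying a multi-copy
(pro)viral element. A third, smaller component reproduces descriptive
RPKM / fold-change reporting for defense genes. A synthetic-data generator
produces all inputs with machine-readable ground truth; every analysis
stage is validated by exact recovery of what was planted and, where a
brute-force alternative exists, by agreement with an independent oracle.

## Spacer extraction

An amplicon spans leader → third spacer, so a no-event read contains
exactly three repeats. Processing steps, in order:

1. **Length filter** — keep reads strictly longer than 300 bp (default);
   with the default 60 bp leader, 30 bp repeat and 34–40 bp spacers, a
   baseline amplicon (~261 bp) fails and any one-unit expansion (~330 bp)
   passes, so the filter is equivalent to "at least one insertion event".
2. **Orientation** — the 20 terminal bases of the leader are searched on
   both strands by infix edit-distance alignment (edlib); best distance ≤ 4
   wins, a tie or no hit marks the read `ambiguous_orientation`.
3. **Repeat counting** — all non-overlapping occurrences of the repeat with
   at most 2 substitutions (no indels), chosen greedily left-to-right.
   The tolerance is a parameter; 2 tolerates sequencing error without
   spurious matches in ~37 nt spacers. Occurrences are deterministic:
   leftmost start wins on overlap.
4. **Extraction** — reads with more repeats than baseline yield the
   sequence strictly between the two leader-proximal repeats. Fragments
   < 10 bp or > 45 bp are excluded (`too_short` / `too_long`); reads with
   more than one extra repeat still yield only the leader-proximal insert.

Properties verified by tests: exact round-trip at error rate 0 (recovered
kept spacers = planted insertions), strand invariance, and monotonicity of
occurrence count in the mismatch tolerance.

## Duplicate / new classification

A spacer within **ten mismatches** of any spacer in any original array (on
either strand) is a duplicate; otherwise it is a new acquisition. The
distance is Hamming for equal lengths and unit-cost edit distance when
lengths differ (`metric="auto"`); pure-edit and Hamming-only variants are
flags, since whether the original ten-mismatch screen allowed indels is
not documented. Ties at the minimum distance resolve to the lowest
(array, spacer-index). Per-array statistics report n_new, n_duplicate,
their ratio (undefined — never infinite — when no duplicates exist), the
duplicate mismatch histogram, and the fraction of duplicates with ≥ 2
mismatches. Classification is memoised per distinct sequence, which makes
duplicate-dominated assays (tens of thousands of reads) fast.

## Protospacer mapping and PAM

Short-query nucleotide search in the conventional style: exact 7-mer seeds
anchor candidate diagonals on both strands; each plausible diagonal is
refined with a gapped local alignment (match +1, mismatch −3, gap open −5,
gap extend −2 per base; Biopython's PairwiseAligner). An ungapped
maximum-segment prescreen discards diagonals whose best contiguous segment
scores below max(10, half the best ungapped score) — such diagonals cannot
produce a competitive alignment — and hits within 90% of the best raw
score are retained. Four strict filters follow: identity > 95%,
mismatches < 4, alignment length / query length > 0.9, and |query span −
query length| < 3 (the length difference is computed on the query span;
the choice matters only for gapped hits). Among passing hits the unique
top raw score wins; an exact tie excludes the spacer from location and PAM
summaries; raw score, not a bit-scaled score, ranks hits — monotone
equivalent for fixed scoring. E-values are not computed.

The PAM is read from the *reference* (not the read): 3 bases immediately
5' of the protospacer on the protospacer strand (length and side are
flags; 5' is the type I convention). Hits at a replicon end with no room
for the window report no PAM. Summaries report per-motif counts against
the trinucleotide composition of the reference (both strands) and binned
protospacer locations with the top locus fraction.

The seeded mapper is verified against a brute-force oracle that scans
every offset on both strands computing ungapped maximum-scoring segments;
with queries carrying ≤ 3 substitutions a 7-mer seed always survives
(pigeonhole over a ≥ 34 nt query), so agreement is exact on status, locus,
identity and mismatch count.

## Coverage, element calling and topology

Reads are mapped by unique exact 21-mer seeds (three per strand: both ends
and the middle) with ungapped verification allowing ≤ 3 substitutions;
reads with repeated seeds or conflicting placements are dropped, so
two-copy repeats contribute nothing. Alignments may also be supplied as
SAM (pysam), which yields byte-identical profiles for the same placements.

Depth is summarised in 500 bp windows (configurable). The baseline is the
**median** window depth, refined by a second pass that drops windows above
twice the first-pass median: an arithmetic "genome average" — and even a
single-pass median in small genomes — is inflated by the element itself.
Calls are maximal runs of ≥ 2 consecutive windows at ≥ 2.5-fold enrichment
(both configurable; 2.5 brackets the weakest real replicating elements
reported in such genomes). The fold estimate for a call averages the
interior windows of the run, because the first and last windows straddle
the element edges and are diluted by flanking baseline coverage.

Topology typing deliberately avoids fixed junction k-mers built from call
coordinates, because calls are window-quantized and the exact junction
sequence is unknowable from a call. Instead:

* **circular** evidence counts reads without a contiguous placement whose
  5' anchor 21-mer places *after* their 3' anchor on the call's replicon —
  back-to-front geometry only produced by reads crossing a circular
  end-to-start junction (the sequencing analogue of outward-facing
  primers);
* **integrated** evidence counts contiguously placed reads spanning a call
  edge by ≥ 10 bp on each side. Because any interval in a reference that
  embeds the element trivially has edge-spanning reads, integration
  evidence is only counted for calls at ≥ 2.5-fold enrichment, and an edge
  at a replicon boundary is *not assessable* (`None`, distinct from zero).

Each evidence type needs ≥ 3 reads (configurable). Known limitation: when
a sample contains only the circular form but is mapped against a reference
in which the element is embedded, baseline host coverage across the locus
would still produce integration evidence; typing is therefore meaningful
relative to the reference form, and the generator emits the circular form
as its own replicon for circular-only simulations (as one would after
resolving the assembly graph).

## Expression

RPKM = c / ((L/1000)(N/10⁶)); what N counts (reads on coding sequences or
genome-wide) is an input, not a guess. Fold increase (cured/infected) is
rounded half-up to two decimals, the dominant convention of the published
defense-gene table bundled as `DEFENSE_GENE_RPKM`; three of its nine rows
print a fold that half-up rounding of the printed RPKM pair does not
reproduce (consistent with truncation or pre-rounding inputs) and are
flagged in `CONSISTENT_ROUNDING_GENES`'s complement rather than chased.
Differential-expression testing is out of scope.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* the analyses assume:

* i.i.d. host sequence at a configurable GC (default 0.60, haloarchaeal
  range), ≥ 10 kb replicons; a planted element (default 10 kb, copy
  number 20, mode `both`) embedded at a recorded locus and/or emitted as a
  standalone circular replicon;
* amplicons with three baseline repeats; per-read probabilities of one
  acquisition (default 0.05), one duplication (default 0.30, mutations per
  duplicate drawn from {0: 0.90, 1: 0.04, 2: 0.03, 3: 0.03}, giving 6%
  multi-mutated duplicates), or one sourceless off-target insert (default
  0); acquisitions are sampled only where the genome provides a 5'-TTC
  window (optionally restricted to the element interval, which reproduces
  the observed locus skew); spacer lengths 34–40 bp bracket the 37 nt
  leader-proximal spacers of natural isolates;
* substitution-only sequencing errors (merged MiSeq amplicons are
  indel-poor and the duplicate screen is mismatch-based; indels are off by
  default), half of all reads reverse-complemented, flat Q30 qualities
  (quality filtering is modelled as already applied upstream);
* shotgun reads at uniform depth (default 30×) with the element at
  copy_number × depth: extra copies are drawn from the circular form
  (wrapping the junction) or across the integrated locus, with start-
  position density chosen so interior depth is exactly copy_number ×
  depth;
* count tables inverted from target RPKMs up to integer rounding.

Not modelled: PCR chimeras, size-selection enrichment, platform-specific
error profiles, indel errors (optional flag territory), polyploidy, and
RNA-seq reads. Passing tests therefore demonstrate correctness of the
*algorithms* under the stated noise model, not robustness to every
artefact of real libraries.

## Problem sizes and numerical choices

Recovery experiments run at: 2,000 amplicons for exact round-trip; 5,000
amplicons (~500 acquisitions) for PAM recovery at error rates 0 and 0.005;
2,500 amplicons for locus skew; 50,000 amplicons for ratio re-estimation
at planted new:duplicate ratios of 0.05 and 0.0006 (checked against exact
binomial confidence bands); 100 kb genomes with 10 kb elements at 30×
depth, 20 seeds, for copy-number recovery at 20× and detection at
2.5–3.5×. These sizes give comfortably powered checks while keeping the
whole suite around a minute. All simulations are driven by a single
`numpy` Generator per run and are byte-reproducible from the seed.

Tie-breaking is deterministic everywhere (leftmost repeat occurrence,
lowest (array, index) in classification, coordinate-sorted alignment
candidates). Degenerate inputs fail loudly: empty references, zero-length
genes or libraries, non-positive windows, overlapping repeat matches, and
acquisition requests against a PAM-free source all raise `ValueError`
rather than returning partial results; empty summaries warn and return
empty containers.
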