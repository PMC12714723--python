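"""Synthetic genomes, CRISPR arrays, amplicon and WGS reads with ground truth.

The generator emulates the data a spacer-acquisition assay produces for a
chronically infected haloarchaeon:

* a host genome carrying a (pro)viral element at elevated copy number, in
  circular and/or integrated form;
* leader-anchored repeat-spacer amplicons with three baseline repeats, a
  fraction of which carry one extra spacer+repeat unit — either a new spacer
  sourced from the genome next to a PAM trinucleotide (default TTC, 5' of
  the protospacer) or a mutated duplicate of an existing spacer;
* whole-genome shotgun reads whose depth reflects the element copy number,
  including reads spanning the circular end-to-start junction and the
  host-element integration edges;
* per-gene count tables engineered to yield chosen RPKM values.

Every planted event is logged in a machine-readable :class:`GroundTruth`
so downstream recovery can be scored exactly.  All sampling is driven by a
single :class:`numpy.random.Generator`; a fixed seed reproduces the output
byte for byte.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .extraction import CrisprArray, MIN_SPACER_LENGTH, MAX_SPACER_LENGTH
from .fileio import SeqRead, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
#: Name given to the standalone circular element replicon when one is emitted.
CIRCULAR_ELEMENT_NAME = "element_circular"


def random_sequence(rng: np.random.Generator, length: int, gc_fraction: float = 0.5) -> str:
    """An i.i.d. random DNA string at the requested GC content."""
    if length <= 0:
        raise ValueError("sequence length must be positive")
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    idx = rng.choice(4, size=length, p=[at, gc, gc, at])
    return _BASES[idx].tobytes().decode("ascii")


def _mutate(seq: str, n_mutations: int, rng: np.random.Generator) -> str:
    """Apply exactly ``n_mutations`` substitutions at distinct positions."""
    if n_mutations == 0:
        return seq
    if n_mutations > len(seq):
        raise ValueError("cannot place more mutations than positions")
    positions = rng.choice(len(seq), size=n_mutations, replace=False)
    out = list(seq)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[rng.integers(3)]
    return "".join(out)


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    """Substitution-only sequencing errors at a per-base rate."""
    if error_rate <= 0:
        return seq
    n_errors = rng.binomial(len(seq), error_rate)
    if n_errors == 0:
        return seq
    return _mutate(seq, int(n_errors), rng)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic experiment.

    ``acquisition_rate``, ``duplication_rate`` and ``off_target_rate`` are
    per-read probabilities of planting, respectively, a genome-sourced new
    spacer (with the PAM immediately 5' of the protospacer), a mutated copy
    of an existing array spacer, and a sourceless random spacer.
    ``duplication_mutation_distribution`` maps a mismatch count to the
    probability that a planted duplicate carries that many substitutions.
    ``acquisition_source`` restricts protospacer sampling to the planted
    element interval when set to ``"element"``.
    """

    seed: int = 0
    genome_lengths: Sequence[int] = (100_000,)
    gc_fraction: float = 0.6
    element_length: int = 10_000
    element_copy_number: float = 20.0
    element_mode: str = "both"  # circular | integrated | both
    n_amplicon_reads: int = 2_000
    acquisition_rate: float = 0.05
    duplication_rate: float = 0.30
    off_target_rate: float = 0.0
    acquisition_source: str = "genome"  # genome | element
    duplication_mutation_distribution: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.90, 1: 0.04, 2: 0.03, 3: 0.03}
    )
    pam_motif: str = "TTC"
    per_base_error_rate: float = 0.0
    read_length: int = 150
    wgs_depth: float = 30.0
    spacer_length_range: tuple[int, int] = (34, 40)

    def validate(self) -> None:
        if any(length <= 0 for length in self.genome_lengths):
            raise ValueError("genome lengths must be positive")
        if self.element_length <= 0:
            raise ValueError("element length must be positive")
        if self.element_mode not in ("circular", "integrated", "both"):
            raise ValueError(f"unknown element_mode {self.element_mode!r}")
        if self.element_copy_number < 1:
            raise ValueError("element copy number must be >= 1")
        for name in ("acquisition_rate", "duplication_rate", "off_target_rate",
                     "per_base_error_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.acquisition_rate + self.duplication_rate + self.off_target_rate > 1.0:
            raise ValueError("per-read event probabilities exceed 1")
        total = sum(self.duplication_mutation_distribution.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("duplication mutation probabilities must sum to 1")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if self.acquisition_source not in ("genome", "element"):
            raise ValueError(f"unknown acquisition_source {self.acquisition_source!r}")
        lo, hi = self.spacer_length_range
        if lo > hi or lo <= 0:
            raise ValueError("invalid spacer_length_range")

    @classmethod
    def from_json(cls, path: str) -> "SimulationConfig":
        with open(path) as handle:
            data = json.load(handle)
        if "duplication_mutation_distribution" in data:
            data["duplication_mutation_distribution"] = {
                int(k): v for k, v in data["duplication_mutation_distribution"].items()
            }
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class ElementTruth:
    """The planted mobile element (0-based, half-open coordinates)."""

    replicon: str
    start: int
    end: int
    copy_number: float
    mode: str


@dataclass
class AcquisitionTruth:
    """One planted new-spacer event; sourceless (off-target) events carry ``None``."""

    read_id: str
    spacer_sequence: str
    source_replicon: str | None
    source_start: int | None
    source_end: int | None
    source_strand: str | None
    pam_trinucleotide: str | None


@dataclass
class DuplicationTruth:
    """One planted duplicate of an existing spacer (0-based source index)."""

    read_id: str
    source_array: str
    source_index: int
    n_mutations: int
    sequence: str


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery scoring."""

    planted_acquisitions: list[AcquisitionTruth] = field(default_factory=list)
    planted_duplications: list[DuplicationTruth] = field(default_factory=list)
    element: ElementTruth | None = None
    per_gene_expected_rpkm: pd.DataFrame | None = None

    def acquisitions_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(a) for a in self.planted_acquisitions])

    def duplications_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(d) for d in self.planted_duplications])

    @property
    def n_planted_inserts(self) -> int:
        return len(self.planted_acquisitions) + len(self.planted_duplications)


def gen_genome(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], ElementTruth]:
    """Generate host replicons and the planted element.

    The first replicon is the host chromosome.  In ``integrated`` and
    ``both`` modes the element sequence is embedded at a recorded locus
    within the stated chromosome length; in ``circular`` and ``both`` modes
    a standalone circular element replicon (:data:`CIRCULAR_ELEMENT_NAME`)
    is emitted as well.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    for length in cfg.genome_lengths:
        if length < 10_000:
            raise ValueError("replicons shorter than 10 kb are not supported")
    element_seq = random_sequence(rng, cfg.element_length, cfg.gc_fraction)
    replicons: dict[str, str] = {}
    element: ElementTruth
    for i, length in enumerate(cfg.genome_lengths):
        name = f"replicon_{i + 1}"
        if i == 0 and cfg.element_mode in ("integrated", "both"):
            if cfg.element_length >= length - 4_000:
                raise ValueError("element does not fit inside the host chromosome")
            host = random_sequence(rng, length - cfg.element_length, cfg.gc_fraction)
            pos = int(rng.integers(2_000, len(host) - 2_000))
            replicons[name] = host[:pos] + element_seq + host[pos:]
            element = ElementTruth(name, pos, pos + cfg.element_length,
                                   cfg.element_copy_number, cfg.element_mode)
        else:
            replicons[name] = random_sequence(rng, length, cfg.gc_fraction)
    if cfg.element_mode in ("circular", "both"):
        replicons[CIRCULAR_ELEMENT_NAME] = element_seq
        if cfg.element_mode == "circular":
            element = ElementTruth(CIRCULAR_ELEMENT_NAME, 0, cfg.element_length,
                                   cfg.element_copy_number, cfg.element_mode)
    return replicons, element


def host_replicons(replicons: Mapping[str, str]) -> dict[str, str]:
    """The replicons without the standalone circular element contig.

    This is the reference a coverage analysis should map against when the
    element also exists integrated in the chromosome: keeping both copies
    would make every element read multi-mapping.
    """
    return {k: v for k, v in replicons.items() if k != CIRCULAR_ELEMENT_NAME}


def gen_array(
    seed: int | np.random.Generator,
    n_spacers: int = 10,
    repeat_length: int = 30,
    spacer_length_range: tuple[int, int] = (34, 40),
    leader_length: int = 60,
    array_id: str = "A",
    gc_fraction: float = 0.5,
) -> CrisprArray:
    """Generate a CRISPR array: leader, one repeat and distinct ordered spacers.

    Spacer index 0 is leader-proximal.  At least three spacers are required
    because the amplicon primers span the region between the leader and the
    third spacer.  Spacer lengths are drawn uniformly from
    ``spacer_length_range`` (the 34-40 nt default brackets the 37 nt
    leader-proximal spacers seen in natural Haloferax isolates).
    """
    if n_spacers < 3:
        raise ValueError("an array needs at least three spacers")
    lo, hi = spacer_length_range
    if lo < MIN_SPACER_LENGTH or hi > MAX_SPACER_LENGTH:
        warnings.warn(
            "spacer_length_range extends outside [10, 45] bp; such spacers "
            "would be excluded by the downstream length filter",
            stacklevel=2,
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    leader = random_sequence(rng, leader_length, gc_fraction)
    repeat = random_sequence(rng, repeat_length, gc_fraction)
    spacers: list[str] = []
    seen = set()
    while len(spacers) < n_spacers:
        length = int(rng.integers(lo, hi + 1))
        spacer = random_sequence(rng, length, gc_fraction)
        if spacer not in seen:
            seen.add(spacer)
            spacers.append(spacer)
    return CrisprArray(array_id, leader, repeat, spacers)


def _pam_sites(
    replicons: Mapping[str, str],
    pam: str,
    max_spacer_length: int,
    element: ElementTruth | None = None,
) -> list[tuple[str, int, str]]:
    """All protospacer anchor sites whose 5'-adjacent trinucleotide equals the PAM.

    Returns ``(replicon, anchor, strand)`` where ``anchor`` is the protospacer
    start for ``+`` sites and the protospacer end (half-open) for ``-`` sites.
    When ``element`` is given, only sites whose maximal protospacer window
    lies inside the element interval are returned.
    """
    sites: list[tuple[str, int, str]] = []
    pam_rc = revcomp(pam)
    for name, seq in replicons.items():
        if element is not None and name != element.replicon:
            continue
        lo = element.start if element is not None else 0
        hi = element.end if element is not None else len(seq)
        # forward strand: PAM at [p, p+3), protospacer starts at p+3
        pos = seq.find(pam)
        while pos != -1:
            anchor = pos + len(pam)
            if anchor >= lo + len(pam) and anchor + max_spacer_length <= hi:
                sites.append((name, anchor, "+"))
            pos = seq.find(pam, pos + 1)
        # reverse strand: protospacer is [anchor-L, anchor) on '-', PAM at [anchor, anchor+3)
        pos = seq.find(pam_rc)
        while pos != -1:
            anchor = pos
            if anchor - max_spacer_length >= lo and anchor + len(pam) <= hi:
                sites.append((name, anchor, "-"))
            pos = seq.find(pam_rc, pos + 1)
    return sites


def simulate_acquisition_reads(
    array: CrisprArray,
    replicons: Mapping[str, str],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    element: ElementTruth | None = None,
) -> tuple[list[SeqRead], GroundTruth]:
    """Simulate merged amplicon reads with planted acquisition/duplication events.

    Each read is the baseline amplicon or carries one extra spacer+repeat unit
    at the leader end.  Substitution errors are applied at the configured
    per-base rate, and half the reads are emitted reverse-complemented to
    force the extractor's orientation handling.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    source_element = element if cfg.acquisition_source == "element" else None
    lo, hi = cfg.spacer_length_range
    sites = _pam_sites(replicons, cfg.pam_motif, hi, source_element)
    if cfg.acquisition_rate > 0 and not sites:
        raise ValueError(
            f"no {cfg.pam_motif}-flanked protospacer window of length {hi} "
            "exists in the requested source region"
        )
    mut_counts = np.array(sorted(cfg.duplication_mutation_distribution))
    mut_probs = np.array([cfg.duplication_mutation_distribution[k] for k in mut_counts])

    baseline = array.baseline_amplicon()
    repeat = array.repeat
    leader_len = len(array.leader)
    truth = GroundTruth(element=element)
    reads: list[SeqRead] = []
    for i in range(cfg.n_amplicon_reads):
        read_id = f"amp_{i:06d}"
        draw = rng.random()
        insert: str | None = None
        if draw < cfg.acquisition_rate:
            replicon, anchor, strand = sites[rng.integers(len(sites))]
            length = int(rng.integers(lo, hi + 1))
            seq = replicons[replicon]
            if strand == "+":
                start, end = anchor, anchor + length
                insert = seq[start:end]
                pam = seq[start - len(cfg.pam_motif):start]
            else:
                start, end = anchor - length, anchor
                insert = revcomp(seq[start:end])
                pam = revcomp(seq[end:end + len(cfg.pam_motif)])
            truth.planted_acquisitions.append(
                AcquisitionTruth(read_id, insert, replicon, start, end, strand, pam)
            )
        elif draw < cfg.acquisition_rate + cfg.duplication_rate:
            index = int(rng.integers(len(array.spacers)))
            n_mut = int(mut_counts[rng.choice(len(mut_counts), p=mut_probs)])
            insert = _mutate(array.spacers[index], n_mut, rng)
            truth.planted_duplications.append(
                DuplicationTruth(read_id, array.array_id, index, n_mut, insert)
            )
        elif draw < cfg.acquisition_rate + cfg.duplication_rate + cfg.off_target_rate:
            length = int(rng.integers(lo, hi + 1))
            insert = random_sequence(rng, length, cfg.gc_fraction)
            truth.planted_acquisitions.append(
                AcquisitionTruth(read_id, insert, None, None, None, None, None)
            )
        if insert is None:
            read_seq = baseline
        else:
            read_seq = (array.leader + repeat + insert + baseline[leader_len:])
        read_seq = _apply_errors(read_seq, cfg.per_base_error_rate, rng)
        if rng.random() < 0.5:
            read_seq = revcomp(read_seq)
        reads.append(SeqRead(read_id, read_seq))
    return reads, truth


def _circular_read(seq: str, start: int, length: int) -> str:
    doubled = seq + seq
    return doubled[start:start + length]


def simulate_wgs(
    replicons: Mapping[str, str],
    element: ElementTruth | None,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[SeqRead]:
    """Simulate whole-genome shotgun reads with the element at elevated depth.

    Host replicons are sampled uniformly at ``wgs_depth``.  The element
    contributes ``copy_number`` times that depth in total: extra copies are
    drawn from the circular form (reads may span the end-to-start junction)
    in ``circular``/``both`` modes, or from the embedded locus (reads may
    span the host-element edges, never the circular junction) in
    ``integrated`` mode.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    rl = cfg.read_length
    if cfg.wgs_depth <= 0:
        raise ValueError("wgs_depth must be positive")
    reads: list[SeqRead] = []
    counter = 0

    def emit(seq: str) -> None:
        nonlocal counter
        seq = _apply_errors(seq, cfg.per_base_error_rate, rng)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append(SeqRead(f"wgs_{counter:07d}", seq))
        counter += 1

    for name, seq in replicons.items():
        if name == CIRCULAR_ELEMENT_NAME:
            continue
        if rl > len(seq):
            raise ValueError("read length exceeds replicon length")
        n_reads = round(cfg.wgs_depth * len(seq) / rl)
        for start in rng.integers(0, len(seq) - rl + 1, size=n_reads):
            emit(seq[start:start + rl])

    if element is None:
        return reads
    extra_copies = cfg.element_copy_number - 1
    if element.mode == "circular":
        # the element was never part of the host sampling loop above
        extra_copies = cfg.element_copy_number
    if extra_copies <= 0:
        return reads
    element_len = element.end - element.start
    if rl > element_len:
        raise ValueError("read length exceeds element length")
    if element.mode in ("circular", "both"):
        n_extra = round(extra_copies * cfg.wgs_depth * element_len / rl)
        if element.mode == "circular":
            circ_seq = replicons[element.replicon]
        else:
            circ_seq = replicons[element.replicon][element.start:element.end]
        for start in rng.integers(0, element_len, size=n_extra):
            emit(_circular_read(circ_seq, int(start), rl))
    else:  # integrated: linear oversampling across the locus and its edges
        seq = replicons[element.replicon]
        lo = max(0, element.start - rl + 1)
        hi = min(len(seq) - rl, element.end - 1)
        # start-position density chosen so interior depth is exactly
        # extra_copies * wgs_depth (reads near the edges spill outside)
        n_extra = round(extra_copies * cfg.wgs_depth * (hi - lo + 1) / rl)
        for start in rng.integers(lo, hi + 1, size=n_extra):
            emit(seq[start:start + rl])
    return reads


def simulate_counts(
    target_rpkm: pd.DataFrame,
    library_sizes: Mapping[str, float],
) -> pd.DataFrame:
    """Invert the RPKM formula to produce integer count tables.

    ``target_rpkm`` needs columns ``gene_id``, ``length`` and one RPKM column
    per condition named in ``library_sizes``.  Returns the same frame with
    ``count_<condition>`` columns whose RPKM (at the given library sizes)
    reproduces the targets up to count rounding.
    """
    out = target_rpkm.copy()
    for condition, total in library_sizes.items():
        rpkm_col = out[condition].astype(float)
        counts = rpkm_col * (out["length"] / 1_000.0) * (total / 1e6)
        out[f"count_{condition}"] = counts.round().astype(int)
    return out
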