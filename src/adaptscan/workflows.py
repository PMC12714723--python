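"""End-to-end orchestration of the synthetic assays.

These helpers wire the generator into the analysis modules the way a real
experiment would be processed: simulate, extract, classify, map; or
simulate shotgun reads, map, profile, call and type elements.  They exist
so recovery experiments are expressed once and reused by tests, scripts
and the CLI.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .classify import acquisition_stats, classify_spacers
from .coverage import (
    ElementCall,
    ReadMapper,
    call_elements,
    depth_profile,
    junction_typing,
    map_reads,
)
from .extraction import CrisprArray, extract_spacers
from .fileio import SeqRead
from .mapping import map_new_spacers, pam_summary
from .simulate import (
    ElementTruth,
    GroundTruth,
    SimulationConfig,
    gen_array,
    gen_genome,
    host_replicons,
    simulate_acquisition_reads,
    simulate_wgs,
)


@dataclass
class AcquisitionAssay:
    """Everything produced by one simulated spacer-acquisition experiment."""

    config: SimulationConfig
    array: CrisprArray
    replicons: dict[str, str]
    element: ElementTruth
    reads: list[SeqRead]
    truth: GroundTruth
    extracted: pd.DataFrame
    classified: pd.DataFrame
    mapped: pd.DataFrame | None = None

    @property
    def stats(self):
        return acquisition_stats(self.classified)


def run_acquisition_assay(
    cfg: SimulationConfig,
    array: CrisprArray | None = None,
    map_spacers: bool = False,
    max_mismatches: int = 10,
) -> AcquisitionAssay:
    """Simulate an acquisition assay and push it through extraction + classification.

    With ``map_spacers`` the new spacers are also aligned back to the host
    replicons and annotated with PAMs.
    """
    replicons, element = gen_genome(cfg)
    if array is None:
        array = gen_array(cfg.seed, spacer_length_range=cfg.spacer_length_range)
    reads, truth = simulate_acquisition_reads(array, replicons, cfg, element=element)
    extracted = extract_spacers(reads, array)
    classified = classify_spacers(extracted, [array], max_mismatches=max_mismatches)
    mapped = None
    if map_spacers:
        new = classified[classified["label"] == "new"]
        mapped = map_new_spacers(new, replicons, pam_length=len(cfg.pam_motif))
    return AcquisitionAssay(cfg, array, replicons, element, reads, truth,
                            extracted, classified, mapped)


@dataclass
class CoverageAssay:
    """One simulated shotgun experiment with its element calls."""

    config: SimulationConfig
    replicons: dict[str, str]       # mapping reference actually used
    element: ElementTruth
    reads: list[SeqRead]
    profile: "pd.DataFrame"
    robust_genome_mean: float
    calls: list[ElementCall] = field(default_factory=list)
    typed_calls: list[ElementCall] = field(default_factory=list)


def run_coverage_assay(
    cfg: SimulationConfig,
    threshold: float = 2.5,
    min_windows: int = 2,
    window_size: int = 500,
    type_junctions: bool = True,
) -> CoverageAssay:
    """Simulate shotgun reads, map, profile, call and (optionally) type elements.

    In ``circular`` mode the standalone element replicon is part of the
    mapping reference (the resolved circular form); otherwise coverage is
    computed against the host chromosome only.
    """
    replicons, element = gen_genome(cfg)
    reads = simulate_wgs(replicons, element, cfg)
    reference = replicons if cfg.element_mode == "circular" else host_replicons(replicons)
    mapper = ReadMapper(reference)
    lengths = {name: len(seq) for name, seq in reference.items()}
    alignments = map_reads(reads, reference, mapper=mapper)
    profile = depth_profile(alignments, lengths, window_size)
    calls = call_elements(profile, threshold, min_windows)
    typed = []
    if type_junctions:
        typed = [junction_typing(reads, call, reference, mapper=mapper)
                 for call in calls]
    return CoverageAssay(cfg, reference, element, reads, profile.windows,
                         profile.robust_genome_mean, calls, typed)
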