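"""Generator contracts: determinism, planted-event bookkeeping, PAM placement."""
import numpy as np
import pytest

from adaptscan.fileio import revcomp
from adaptscan.simulate import (
    CIRCULAR_ELEMENT_NAME,
    SimulationConfig,
    gen_array,
    gen_genome,
    host_replicons,
    simulate_acquisition_reads,
    simulate_counts,
    simulate_wgs,
)


def _amplicon_config(**overrides):
    defaults = dict(seed=42, genome_lengths=(40_000,), element_length=5_000,
                    element_mode="integrated", n_amplicon_reads=400)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestGenGenome:
    def test_integrated_element_recorded_within_stated_length(self):
        cfg = SimulationConfig(seed=1, genome_lengths=(50_000,), element_length=5_000,
                               element_mode="integrated")
        replicons, element = gen_genome(cfg)
        assert len(replicons["replicon_1"]) == 50_000
        assert 0 < element.start < element.end <= 50_000
        assert element.end - element.start == 5_000

    def test_same_seed_is_byte_identical(self):
        cfg = SimulationConfig(seed=9, genome_lengths=(12_000,), element_length=2_000,
                               element_mode="both", n_amplicon_reads=50)
        out1 = gen_genome(cfg)
        out2 = gen_genome(cfg)
        assert out1[0] == out2[0]
        assert out1[1] == out2[1]

    def test_mode_both_emits_embedded_and_circular_copies(self):
        cfg = SimulationConfig(seed=2, genome_lengths=(30_000,), element_length=4_000,
                               element_mode="both")
        replicons, element = gen_genome(cfg)
        circular = replicons[CIRCULAR_ELEMENT_NAME]
        embedded = replicons[element.replicon][element.start:element.end]
        assert circular == embedded
        assert host_replicons(replicons) == {
            "replicon_1": replicons["replicon_1"]}

    def test_rejects_bad_lengths(self):
        with pytest.raises(ValueError):
            gen_genome(SimulationConfig(genome_lengths=(0,)))
        with pytest.raises(ValueError):
            gen_genome(SimulationConfig(genome_lengths=(5_000,)))

    def test_gc_content_matches_request(self):
        cfg = SimulationConfig(seed=3, genome_lengths=(50_000,), element_length=5_000,
                               element_mode="circular", gc_fraction=0.6)
        replicons, _ = gen_genome(cfg)
        seq = replicons["replicon_1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.6) < 0.02


class TestGenArray:
    def test_baseline_amplicon_structure(self):
        array = gen_array(5, n_spacers=3, repeat_length=30)
        expected = (array.leader + array.repeat + array.spacers[0]
                    + array.repeat + array.spacers[1]
                    + array.repeat + array.spacers[2])
        assert array.baseline_amplicon() == expected

    def test_default_lengths_cover_the_37nt_leader_proximal_spacer(self):
        array = gen_array(5, n_spacers=40)
        lengths = {len(s) for s in array.spacers}
        assert 37 in lengths
        assert lengths <= set(range(34, 41))

    def test_different_seeds_give_disjoint_spacer_sets(self):
        a = gen_array(1, n_spacers=20)
        b = gen_array(2, n_spacers=20)
        assert not set(a.spacers) & set(b.spacers)

    def test_out_of_band_spacer_lengths_warn(self):
        with pytest.warns(UserWarning):
            gen_array(5, spacer_length_range=(5, 9))

    def test_too_few_spacers_rejected(self):
        with pytest.raises(ValueError):
            gen_array(5, n_spacers=2)


class TestAcquisitionReads:
    def test_zero_rates_yield_only_baseline_amplicons(self, default_array):
        cfg = _amplicon_config(acquisition_rate=0.0, duplication_rate=0.0)
        replicons, element = gen_genome(cfg)
        reads, truth = simulate_acquisition_reads(default_array, replicons, cfg,
                                                  element=element)
        baseline = default_array.baseline_amplicon()
        assert truth.n_planted_inserts == 0
        assert all(r.seq in (baseline, revcomp(baseline)) for r in reads)

    def test_truth_records_match_non_baseline_reads(self, default_array):
        cfg = _amplicon_config(acquisition_rate=0.1, duplication_rate=0.3)
        replicons, element = gen_genome(cfg)
        reads, truth = simulate_acquisition_reads(default_array, replicons, cfg,
                                                  element=element)
        baseline = default_array.baseline_amplicon()
        n_expanded = sum(r.seq not in (baseline, revcomp(baseline)) for r in reads)
        assert truth.n_planted_inserts == n_expanded

    def test_planted_pam_is_adjacent_in_genome(self, default_array):
        cfg = _amplicon_config(acquisition_rate=0.3, duplication_rate=0.0)
        replicons, element = gen_genome(cfg)
        _, truth = simulate_acquisition_reads(default_array, replicons, cfg,
                                              element=element)
        assert truth.planted_acquisitions
        for acq in truth.planted_acquisitions:
            seq = replicons[acq.source_replicon]
            if acq.source_strand == "+":
                flank = seq[acq.source_start - 3:acq.source_start]
                assert acq.spacer_sequence == seq[acq.source_start:acq.source_end]
            else:
                flank = revcomp(seq[acq.source_end:acq.source_end + 3])
                assert acq.spacer_sequence == revcomp(
                    seq[acq.source_start:acq.source_end])
            assert flank == cfg.pam_motif == acq.pam_trinucleotide

    def test_element_restricted_sourcing(self, default_array):
        cfg = _amplicon_config(acquisition_rate=0.3, duplication_rate=0.0,
                               acquisition_source="element")
        replicons, element = gen_genome(cfg)
        _, truth = simulate_acquisition_reads(default_array, replicons, cfg,
                                              element=element)
        for acq in truth.planted_acquisitions:
            assert acq.source_replicon == element.replicon
            assert element.start <= acq.source_start < acq.source_end <= element.end

    def test_fails_without_any_pam_site(self, default_array):
        cfg = _amplicon_config(acquisition_rate=0.2)
        with pytest.raises(ValueError, match="TTC"):
            simulate_acquisition_reads(default_array, {"replicon_1": "A" * 20_000}, cfg)

    def test_determinism(self, default_array):
        cfg = _amplicon_config(acquisition_rate=0.05, per_base_error_rate=0.002)
        replicons, element = gen_genome(cfg)
        r1, t1 = simulate_acquisition_reads(default_array, replicons, cfg, element=element)
        r2, t2 = simulate_acquisition_reads(default_array, replicons, cfg, element=element)
        assert [(r.id, r.seq) for r in r1] == [(r.id, r.seq) for r in r2]
        assert t1.acquisitions_frame().equals(t2.acquisitions_frame())


class TestWgs:
    def test_circular_mode_emits_junction_spanning_reads(self):
        cfg = SimulationConfig(seed=8, genome_lengths=(30_000,), element_length=4_000,
                               element_mode="circular", element_copy_number=20,
                               wgs_depth=30)
        replicons, element = gen_genome(cfg)
        reads = simulate_wgs(replicons, element, cfg)
        elem = replicons[CIRCULAR_ELEMENT_NAME]
        doubled = elem + elem
        wrap = [r for r in reads
                if (r.seq in doubled or revcomp(r.seq) in doubled)
                and r.seq not in elem and revcomp(r.seq) not in elem]
        assert len(wrap) >= 1

    def test_read_length_longer_than_replicon_rejected(self):
        cfg = SimulationConfig(seed=8, genome_lengths=(12_000,), element_length=2_000,
                               element_mode="integrated", read_length=20_000)
        replicons, element = gen_genome(cfg)
        with pytest.raises(ValueError):
            simulate_wgs(replicons, element, cfg)


def test_simulate_counts_inverts_rpkm():
    import pandas as pd
    from adaptscan.expression import expression_table

    targets = pd.DataFrame({
        "gene_id": ["g1", "g2"], "length": [900, 2_400],
        "cured": [120.0, 45.85], "infected": [7.35, 5.53],
    })
    libraries = {"cured": 2_000_000, "infected": 1_500_000}
    counts = simulate_counts(targets, libraries)
    table = expression_table(counts, libraries)
    assert np.allclose(table["rpkm_cured"], targets["cured"], rtol=0.01)
    assert np.allclose(table["rpkm_infected"], targets["infected"], rtol=0.01)
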