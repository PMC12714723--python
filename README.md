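# adaptscan

Tools for quantifying CRISPR spacer acquisition and replicating mobile
elements in chronically infected archaea — the computational side of a
spacer-acquisition assay plus the genomic evidence that goes with it.

Haloarchaea such as *Haloferax* often carry chronic (pro)viral infections.
Two sequencing read-outs reveal what the virus is doing to host immunity:

1. **Spacer-acquisition amplicons.** Primers spanning the region between a
   CRISPR array's leader and its third spacer produce a fixed-size product;
   a read with one extra repeat carries a newly inserted spacer+repeat unit
   at the leader end. Most inserts are *duplications* of spacers already in
   the arrays (within ten mismatches); only inserts with no resemblance to
   any existing spacer are *new acquisitions*. New spacers map back to a
   protospacer in the genome, flanked 5' by a TTC protospacer-adjacent
   motif (PAM) in these type I systems, and their genomic locations are
   typically highly skewed toward one invading element.
2. **Whole-genome shotgun coverage.** A replicating element shows up as a
   run of windows whose depth is a multiple of the genome-wide baseline
   (median window depth), and its topology — circular, integrated, or both
   — is typed from junction-spanning reads: back-to-front split reads are
   the sequencing analogue of an outward-facing PCR across the circular
   end-to-start junction, while contiguous reads across a host–element
   edge evidence an integrated copy.

The package implements both pipelines end to end, a defense-gene RPKM /
fold-change report (RPKM = c / ((L/1000)·(N/10⁶)) for c reads on a gene of
length L in a library of N mapped reads), and a synthetic-data generator
that plants acquisitions, duplications and multi-copy elements with full
ground truth, so every stage can be scored by exact recovery.

## Worked example

```python
from adaptscan.simulate import SimulationConfig
from adaptscan.workflows import run_acquisition_assay, run_coverage_assay
from adaptscan.mapping import pam_summary

cfg = SimulationConfig(seed=11, genome_lengths=(50_000,), element_length=8_000,
                       element_mode="both", element_copy_number=20,
                       n_amplicon_reads=2_000, acquisition_rate=0.05,
                       duplication_rate=0.30)

assay = run_acquisition_assay(cfg, map_spacers=True)
stats = assay.stats["A"]
summary = pam_summary(assay.mapped, assay.replicons)

cov = run_coverage_assay(cfg)
call = cov.typed_calls[0]
```

which prints (via the obvious `print` calls):

```
kept spacers: 694
new: 95  duplicates: 599  ratio: 0.1586
duplicate mutation histogram: {0: 544, 1: 25, 2: 17, 3: 12, 10: 1}
fraction multi-mutated: 0.0501
top PAM: TTC  fraction: 1.0  background TTC: 0.0125
element call: replicon_1:39000-47500 enrichment 19.7 topology both
  (circular junction reads 400, integration junction reads 55)
```

Reading this: of 2,000 simulated amplicons, 694 carried an extra
repeat-spacer unit; 599 were duplications of existing spacers (most exact,
5% with ≥2 mutations) and 95 were new acquisitions, all of which mapped
back to their planted protospacers with a uniform TTC PAM (genome-wide TTC
background: 1.25% of trinucleotides). The shotgun arm recovered the planted
20-copy, 8 kb element as a single ~20-fold-enriched call typed as present
in both circular and integrated form.

The same stages are available from the shell:

```bash
adaptscan simulate --config cfg.json --outdir sim/
adaptscan extract  --reads sim/amplicons.fastq --array sim/array.json --out spacers.tsv
adaptscan classify --spacers spacers.tsv --arrays sim/array.json --out classified.tsv
adaptscan map      --spacers new.tsv --ref sim/replicons.fasta --out hits.tsv
adaptscan cov      --reads sim/wgs.fastq --ref sim/replicons.fasta --out profile.tsv
adaptscan express  --counts counts.tsv --out report.tsv
```

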