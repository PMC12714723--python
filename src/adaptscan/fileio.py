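"""Reading and writing of the standard formats (FASTA, FASTQ, TSV) used by the pipeline.

All sequence file I/O goes through Biopython; tabular I/O goes through pandas.
In-memory reads are held as lightweight :class:`SeqRead` records so the hot
loops of the extractor and mapper can work on plain Python strings.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SeqRead:
    """One named sequence (a FASTQ/FASTA record held in memory)."""

    id: str
    seq: str

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.seq)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an ordered ``{name: sequence}`` mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[SeqRead]:
    return [SeqRead(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Iterable[SeqRead], path: str | Path, quality: int = 30) -> None:
    """Write reads as Phred+33 FASTQ with a constant placeholder quality.

    Quality filtering is modelled as already applied upstream of this
    pipeline, so a flat Q30 string is emitted for every base.
    """
    records = []
    for read in reads:
        rec = SeqRecord(Seq(read.seq), id=read.id, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(read.seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)
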