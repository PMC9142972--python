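"""Reading and writing the pipeline's on-disk formats.

FASTA and FASTQ parsing goes through Biopython; writers for the simple
line formats (FASTQ records we generate ourselves, collapsed-read FASTA,
TSV tables) are direct so that fixed seeds give byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .types import CollapsedRead
from .util import to_dna, to_rna


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> ordered dict of id (first header token) -> DNA sequence."""
    return {rec.id: to_dna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """FASTQ -> list of (id, DNA sequence, quality string), Phred+33."""
    with open(path) as fh:
        return [(title.split()[0], to_dna(seq), qual) for title, seq, qual in FastqGeneralIterator(fh)]


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def write_collapsed_fasta(path: str | Path, reads: Iterable[CollapsedRead], library_names: list[str]) -> None:
    """Collapsed reads as FASTA with per-library counts encoded in headers:
    ``>seq<i>_<lib>:<count>..._total:<t>``."""
    with open(path, "w") as fh:
        for i, rec in enumerate(reads, start=1):
            parts = "_".join(f"{lib}:{c}" for lib, c in zip(library_names, rec.counts))
            fh.write(f">seq{i}_{parts}_total:{rec.total}\n{rec.sequence}\n")


def read_mirbase_fasta(path: str | Path) -> dict[str, str]:
    """Reference mature miRNA FASTA in the miRBase dialect (RNA alphabet,
    ``>name accession description`` headers).  Returns name -> DNA sequence;
    comparisons downstream run in DNA space."""
    return read_fasta(path)


def write_mirbase_fasta(path: str | Path, matures: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in matures.items():
            fh.write(f">{name}\n{to_rna(seq)}\n")


def write_tsv(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
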