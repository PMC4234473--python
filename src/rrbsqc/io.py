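"""File I/O: FASTA, FASTQ, BED and fragment tables.

Standard formats go through Biopython; BED is the plain 3+ column, 0-based
half-open dialect used throughout the package.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GenomicInterval, ReferenceGenome, RrbsFragment
from .reads import BisRead

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_bed",
    "write_bed",
    "write_fragments_bed",
]


def read_fasta(path: str | os.PathLike) -> ReferenceGenome:
    """Load a (multi-)FASTA file, case-folding sequences to uppercase."""
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return ReferenceGenome(contigs)


def write_fasta(genome: ReferenceGenome, path: str | os.PathLike, width: int = 70) -> None:
    records = [SeqRecord(Seq(genome[name]), id=name, description="") for name in genome]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    # Biopython wraps at 60 by default which is fine for any downstream parser.


def read_fastq(path: str | os.PathLike) -> list[BisRead]:
    """Parse phred+33 FASTQ into BisRead records (no truth metadata)."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            BisRead(
                read_id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=list(rec.letter_annotations["phred_quality"]),
            )
        )
    return reads


def write_fastq(reads: Iterable[BisRead], path: str | os.PathLike) -> None:
    """Write standard 4-line-per-record FASTQ, phred+33."""
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read 3+ column BED (0-based half-open); strand from column 6 if present."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            strand = cols[5] if len(cols) >= 6 and cols[5] in "+-" else "+"
            intervals.append(GenomicInterval(cols[0], int(cols[1]), int(cols[2]), strand))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def write_fragments_bed(fragments: Sequence[RrbsFragment], path: str | os.PathLike) -> None:
    """Fragment intervals as BED with insert length and internal/terminal flag."""
    with open(path, "w") as fh:
        for f in fragments:
            iv = f.interval
            kind = "internal" if f.flanked_both_ends else "terminal"
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{kind}\t{f.insert_length}\t+\n")
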