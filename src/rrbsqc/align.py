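"""Minimal directional three-letter bisulfite aligner.

Reads from a directional RRBS library derive from the original top (OT) or
original bottom (OB) strand only.  Both the read and the reference are
collapsed to a three-letter alphabet (C→T) before comparison, so a read T
over a genomic C (bisulfite conversion) is not a mismatch while C-over-T and
T-over-C in reduced space remain real mismatches.  Placement is best-unique:
candidates are gathered by exact k-mer seeds in both reduced spaces, scored
by reduced-space mismatch count, and a read is reported ``unique`` only if
exactly one placement attains the minimal count and that count is within
``max_mismatch`` (default 2).  Ties — including ties across strands — make
the read ``ambiguous``; no indels are modelled (RRBS 50-mers from MspI ends
align end-to-end), so CIGARs are always all-match.

With three or more disjoint seed windows and ``max_mismatch=2``, the
pigeonhole principle guarantees every placement within the mismatch budget
is recovered, which makes the seeded search exactly equivalent to a
brute-force scan over all offsets and both strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .genome import (
    CpGSite,
    CytosineContext,
    GenomicInterval,
    ReferenceGenome,
    classify_context,
    revcomp,
)
from .reads import BisRead

__all__ = [
    "AlignStatus",
    "MethylationCall",
    "AlignedRead",
    "BisulfiteIndex",
    "build_index",
    "align_read",
    "align_reads",
    "extract_calls",
    "to_sam",
    "alignments_from_sam",
    "calls_from_sam",
]

_XM_CODE = {
    (CytosineContext.CPG, True): "Z",
    (CytosineContext.CPG, False): "z",
    (CytosineContext.CHG, True): "X",
    (CytosineContext.CHG, False): "x",
    (CytosineContext.CHH, True): "H",
    (CytosineContext.CHH, False): "h",
}
_XM_DECODE = {v: k for k, v in _XM_CODE.items()}


class AlignStatus(str, Enum):
    UNIQUE = "unique"
    AMBIGUOUS = "ambiguous"
    UNALIGNED = "unaligned"


@dataclass(frozen=True)
class MethylationCall:
    """One cytosine observation from one read.

    ``site`` is the forward-strand coordinate of the cytosine; calls at the
    G of a CpG (reverse-strand reads) are re-attributed to the forward C of
    the dinucleotide so both strands tally onto one CpG site.
    """

    site: CpGSite
    context: CytosineContext
    methylated: bool
    read_id: str
    strand: str = "OT"


@dataclass
class AlignedRead:
    read: BisRead
    status: AlignStatus
    placement: GenomicInterval | None = None
    source_strand: str | None = None  # "OT" | "OB"
    mismatches: int | None = None
    calls: list[MethylationCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status is AlignStatus.UNIQUE:
            if self.placement is None or self.source_strand not in ("OT", "OB"):
                raise ValueError("unique alignment requires placement and strand")
        elif self.placement is not None:
            raise ValueError("non-unique alignment must not carry a placement")


class BisulfiteIndex:
    """C→T reduced texts of both strands plus an exact k-mer seed table.

    ``forward_reduced[contig]`` is the C→T forward text; ``reverse_reduced``
    the C→T text of the reverse complement.  The seed table maps every
    ``seed_length``-mer of both texts to its occurrence list.
    """

    def __init__(self, genome: ReferenceGenome, seed_length: int = 16):
        if seed_length < 8:
            raise ValueError("seed_length must be >= 8")
        for name in genome:
            if genome.length(name) < seed_length:
                raise ValueError(f"contig {name!r} shorter than the seed length")
        self.genome = genome
        self.seed_length = seed_length
        self.forward_reduced: dict[str, np.ndarray] = {}
        self.reverse_reduced: dict[str, np.ndarray] = {}
        self._table: dict[bytes, list[tuple[str, str, int]]] = {}
        for name in genome:
            seq = genome[name]
            fwd = np.frombuffer(seq.replace("C", "T").encode(), dtype=np.uint8)
            rev = np.frombuffer(revcomp(seq).replace("C", "T").encode(), dtype=np.uint8)
            self.forward_reduced[name] = fwd
            self.reverse_reduced[name] = rev
            for space, arr in (("fwd", fwd), ("rev", rev)):
                data = arr.tobytes()
                for pos in range(len(data) - seed_length + 1):
                    kmer = data[pos : pos + seed_length]
                    if b"N" in kmer:
                        continue
                    self._table.setdefault(kmer, []).append((name, space, pos))

    def lookup(self, kmer: bytes) -> list[tuple[str, str, int]]:
        return self._table.get(kmer, [])


def build_index(genome: ReferenceGenome, seed_length: int = 16) -> BisulfiteIndex:
    return BisulfiteIndex(genome, seed_length)


def _seed_offsets(read_len: int, seed_len: int) -> list[int]:
    offs = list(range(0, read_len - seed_len + 1, seed_len))
    if not offs:
        return []
    if offs[-1] != read_len - seed_len:
        offs.append(read_len - seed_len)
    return offs


def _scan_all_offsets(
    reduced: np.ndarray, index: BisulfiteIndex, max_mismatch: int
) -> set[tuple[str, str, int]]:
    """Exhaustive candidate generation for reads too short for pigeonhole seeds.

    Vectorised mismatch counting at every offset of both reduced spaces;
    only placements within the mismatch budget are returned, so downstream
    best-stratum logic is unchanged.
    """
    L = len(reduced)
    out: set[tuple[str, str, int]] = set()
    for contig in index.genome:
        for space, text in (
            ("fwd", index.forward_reduced[contig]),
            ("rev", index.reverse_reduced[contig]),
        ):
            n_off = len(text) - L + 1
            if n_off <= 0:
                continue
            mm = np.zeros(n_off, dtype=np.int16)
            for i in range(L):
                mm += reduced[i] != text[i : i + n_off]
            for start in np.nonzero(mm <= max_mismatch)[0]:
                out.add((contig, space, int(start)))
    return out


def align_read(
    read: BisRead,
    index: BisulfiteIndex,
    genome: ReferenceGenome | None = None,
    max_mismatch: int = 2,
) -> AlignedRead:
    """Best-unique directional placement of one read (see module docstring)."""
    genome = genome or index.genome
    L = len(read)
    sl = index.seed_length
    if L < sl:
        return AlignedRead(read=read, status=AlignStatus.UNALIGNED)
    reduced = np.frombuffer(
        read.sequence.replace("C", "T").encode(), dtype=np.uint8
    )
    if L < (max_mismatch + 1) * sl:
        # too short for max_mismatch+1 disjoint seed windows: scan exhaustively
        candidates = _scan_all_offsets(reduced, index, max_mismatch)
    else:
        data = reduced.tobytes()
        candidates = set()
        for off in _seed_offsets(L, sl):
            for contig, space, pos in index.lookup(data[off : off + sl]):
                start = pos - off
                if start >= 0 and start + L <= index.genome.length(contig):
                    candidates.add((contig, space, start))
    if not candidates:
        return AlignedRead(read=read, status=AlignStatus.UNALIGNED)

    best_mm = None
    best_hits: list[tuple[str, str, int]] = []
    for contig, space, start in sorted(candidates):
        text = (
            index.forward_reduced[contig] if space == "fwd" else index.reverse_reduced[contig]
        )
        mm = int(np.count_nonzero(text[start : start + L] != reduced))
        if best_mm is None or mm < best_mm:
            best_mm, best_hits = mm, [(contig, space, start)]
        elif mm == best_mm:
            best_hits.append((contig, space, start))
    if best_mm is None or best_mm > max_mismatch:
        return AlignedRead(read=read, status=AlignStatus.UNALIGNED)
    if len(best_hits) > 1:
        return AlignedRead(read=read, status=AlignStatus.AMBIGUOUS)

    contig, space, start = best_hits[0]
    if space == "fwd":
        placement = GenomicInterval(contig, start, start + L, "+")
        strand = "OT"
    else:
        clen = index.genome.length(contig)
        placement = GenomicInterval(contig, clen - start - L, clen - start, "-")
        strand = "OB"
    aligned = AlignedRead(
        read=read,
        status=AlignStatus.UNIQUE,
        placement=placement,
        source_strand=strand,
        mismatches=best_mm,
    )
    aligned.calls = extract_calls(aligned, genome)
    return aligned


def align_reads(
    reads: Iterable[BisRead],
    index: BisulfiteIndex,
    genome: ReferenceGenome | None = None,
    max_mismatch: int = 2,
) -> list[AlignedRead]:
    return [align_read(r, index, genome, max_mismatch) for r in reads]


def extract_calls(aligned: AlignedRead, genome: ReferenceGenome) -> list[MethylationCall]:
    """Per-cytosine methylation calls for a uniquely placed read.

    For every genomic cytosine on the read's source strand: read base C is a
    methylated call, T a converted call, anything else (sequencing error) no
    call.  Boundary cytosines without two downstream bases, and contexts
    containing N, are skipped.
    """
    if aligned.status is not AlignStatus.UNIQUE:
        raise ValueError("methylation calls require a unique alignment")
    iv = aligned.placement
    seq = genome[iv.contig]
    read_seq = aligned.read.sequence
    calls: list[MethylationCall] = []
    if aligned.source_strand == "OT":
        for i in range(len(iv)):
            gpos = iv.start + i
            if seq[gpos] != "C":
                continue
            base = read_seq[i]
            if base not in ("C", "T"):
                continue
            try:
                ctx = classify_context(genome, iv.contig, gpos, "+")
            except (ValueError, IndexError):
                continue
            calls.append(
                MethylationCall(
                    site=CpGSite(iv.contig, gpos),
                    context=ctx,
                    methylated=(base == "C"),
                    read_id=aligned.read.read_id,
                    strand="OT",
                )
            )
    else:
        for i in range(len(iv)):
            gpos = iv.end - 1 - i  # read coordinate i on the bottom strand
            if seq[gpos] != "G":
                continue
            base = read_seq[i]
            if base not in ("C", "T"):
                continue
            try:
                ctx = classify_context(genome, iv.contig, gpos, "-")
            except (ValueError, IndexError):
                continue
            # a CpG seen from the bottom strand is the G of the forward CpG:
            # attribute the call to the forward-strand C one base upstream
            site_pos = gpos - 1 if ctx is CytosineContext.CPG else gpos
            calls.append(
                MethylationCall(
                    site=CpGSite(iv.contig, site_pos),
                    context=ctx,
                    methylated=(base == "C"),
                    read_id=aligned.read.read_id,
                    strand="OB",
                )
            )
    return calls


def _xm_string(aligned: AlignedRead) -> str:
    """Per-base methylation-call string in reference (SEQ) orientation."""
    iv = aligned.placement
    chars = ["."] * len(iv)
    for call in aligned.calls:
        if call.strand == "OT":
            offset = call.site.pos - iv.start
        else:
            gpos = call.site.pos + 1 if call.context is CytosineContext.CPG else call.site.pos
            offset = gpos - iv.start
        if 0 <= offset < len(iv):
            chars[offset] = _XM_CODE[(call.context, call.methylated)]
    return "".join(chars)


def to_sam(
    aligned_reads: Sequence[AlignedRead],
    genome: ReferenceGenome,
    include_unmapped: bool = False,
) -> str:
    """Render alignments as SAM text (1-based POS, FLAG 16 for OB reads).

    SEQ/QUAL are stored in reference orientation per the SAM convention;
    NM carries the reduced-space mismatch count, XM the per-base methylation
    call string (Z/z CpG, X/x CHG, H/h CHH, '.' otherwise) in reference
    orientation, and XG the strand of origin.
    """
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for name in genome:
        lines.append(f"@SQ\tSN:{name}\tLN:{genome.length(name)}")
    lines.append("@PG\tID:rrbsqc\tPN:rrbsqc")
    for a in aligned_reads:
        if a.status is not AlignStatus.UNIQUE:
            if include_unmapped:
                qual = "".join(chr(q + 33) for q in a.read.qualities)
                lines.append(
                    f"{a.read.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{a.read.sequence}\t{qual}"
                )
            continue
        iv = a.placement
        if iv.contig not in genome:
            raise ValueError(f"contig {iv.contig!r} absent from genome")
        if a.source_strand == "OB":
            flag = 16
            seq = revcomp(a.read.sequence)
            qual = "".join(chr(q + 33) for q in reversed(a.read.qualities))
        else:
            flag = 0
            seq = a.read.sequence
            qual = "".join(chr(q + 33) for q in a.read.qualities)
        lines.append(
            "\t".join(
                [
                    a.read.read_id,
                    str(flag),
                    iv.contig,
                    str(iv.start + 1),
                    "255",
                    f"{len(iv)}M",
                    "*",
                    "0",
                    "0",
                    seq,
                    qual,
                    f"NM:i:{a.mismatches}",
                    f"XM:Z:{_xm_string(a)}",
                    f"XG:Z:{a.source_strand}",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def alignments_from_sam(path) -> list[AlignedRead]:
    """Reconstruct unique alignments (with calls) from a SAM file.

    Accepts any SAM whose records carry the XM/XG methylation-call dialect
    written by :func:`to_sam`; SEQ is flipped back to read orientation for
    FLAG-16 records so duplicate keys match the in-memory pipeline.
    """
    import pysam

    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            strand = rec.get_tag("XG") if rec.has_tag("XG") else ("OB" if rec.is_reverse else "OT")
            seq = rec.query_sequence or ""
            quals = list(rec.query_qualities) if rec.query_qualities is not None else [0] * len(seq)
            if rec.is_reverse:
                seq = revcomp(seq)
                quals = quals[::-1]
            read = BisRead(rec.query_name, seq, quals)
            placement = GenomicInterval(
                rec.reference_name,
                rec.reference_start,
                rec.reference_start + len(seq),
                "-" if rec.is_reverse else "+",
            )
            aligned = AlignedRead(
                read=read,
                status=AlignStatus.UNIQUE,
                placement=placement,
                source_strand=strand,
                mismatches=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
            )
            if rec.has_tag("XM"):
                xm = rec.get_tag("XM")
                for i, ch in enumerate(xm):
                    if ch == ".":
                        continue
                    ctx, meth = _XM_DECODE[ch]
                    gpos = rec.reference_start + i
                    if strand == "OB" and ctx is CytosineContext.CPG:
                        gpos -= 1
                    aligned.calls.append(
                        MethylationCall(
                            site=CpGSite(rec.reference_name, gpos),
                            context=ctx,
                            methylated=meth,
                            read_id=rec.query_name,
                            strand=strand,
                        )
                    )
            out.append(aligned)
    return out


def calls_from_sam(path) -> list[MethylationCall]:
    """Reconstruct methylation calls from a SAM file carrying XM/XG tags."""
    import pysam

    calls: list[MethylationCall] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or not rec.has_tag("XM"):
                continue
            xm = rec.get_tag("XM")
            xg = rec.get_tag("XG") if rec.has_tag("XG") else "OT"
            start = rec.reference_start
            contig = rec.reference_name
            for i, ch in enumerate(xm):
                if ch == ".":
                    continue
                ctx, meth = _XM_DECODE[ch]
                gpos = start + i
                if xg == "OB" and ctx is CytosineContext.CPG:
                    gpos -= 1
                calls.append(
                    MethylationCall(
                        site=CpGSite(contig, gpos),
                        context=ctx,
                        methylated=meth,
                        read_id=rec.query_name,
                        strand=xg,
                    )
                )
    return calls
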