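"""Reference genomes, MspI digestion, and cytosine-context classification.

RRBS restricts the sequenced genome to MspI (C^CGG) fragments.  MspI cuts
between the outer C and the internal CGG, leaving 5'-CG overhangs; end repair
fills these in, so every internal fragment carries a CpG at both ends and its
top strand reads ``CGG ... CCG``.  Everything downstream (simulation,
alignment, methylation calling) is expressed in the 0-based, half-open
coordinate frame defined here; SAM export converts to 1-based on the way out.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping

__all__ = [
    "ReferenceGenome",
    "GenomicInterval",
    "RrbsFragment",
    "CpGSite",
    "CytosineContext",
    "revcomp",
    "find_mspi_sites",
    "digest",
    "size_select",
    "classify_context",
    "find_cpg_sites",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_VALID_BASES = frozenset("ACGTN")

# MspI recognition site on the forward strand; the site is palindromic, so a
# forward scan finds every cut.  Lookahead so CCGGCCGG yields both occurrences.
_MSPI_RE = re.compile(r"(?=CCGG)")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


class ReferenceGenome:
    """An ordered collection of named DNA sequences over {A,C,G,T,N}.

    Sequences are upper-cased on construction.  Contig names must be unique
    and non-empty, and every contig must be at least one base long.
    """

    def __init__(self, contigs: Mapping[str, str]):
        if not contigs:
            raise ValueError("genome must contain at least one contig")
        clean: dict[str, str] = {}
        for name, seq in contigs.items():
            if not name:
                raise ValueError("contig names must be non-empty")
            if name in clean:
                raise ValueError(f"duplicate contig name {name!r}")
            s = str(seq).upper()
            if not s:
                raise ValueError(f"contig {name!r} is empty")
            bad = set(s) - _VALID_BASES
            if bad:
                raise ValueError(f"contig {name!r} contains invalid bases {sorted(bad)}")
            clean[name] = s
        self._contigs = clean

    @property
    def contigs(self) -> dict[str, str]:
        return dict(self._contigs)

    def __contains__(self, name: str) -> bool:
        return name in self._contigs

    def __getitem__(self, name: str) -> str:
        return self._contigs[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._contigs)

    def __len__(self) -> int:
        return len(self._contigs)

    def length(self, name: str) -> int:
        return len(self._contigs[name])

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        parts = ", ".join(f"{n}:{len(s)}bp" for n, s in self._contigs.items())
        return f"ReferenceGenome({parts})"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval [start, end) on a named contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, contig: str, pos: int) -> bool:
        return contig == self.contig and self.start <= pos < self.end


@dataclass(frozen=True)
class RrbsFragment:
    """An end-repaired MspI fragment.

    ``interval`` covers the genomic span between cut positions on the top
    strand; ``top_sequence`` is the physical fragment after fill-in of the
    5'-CG overhangs, which duplicates each boundary CpG into both neighbours.
    For an internal fragment ``len(top_sequence) == len(interval) + 2`` and
    the sequence starts ``CGG`` and ends ``CCG``.
    """

    interval: GenomicInterval
    top_sequence: str
    flanked_both_ends: bool = True

    def __post_init__(self) -> None:
        if self.flanked_both_ends:
            if not (self.top_sequence.startswith("CGG") and self.top_sequence.endswith("CCG")):
                raise ValueError("internal MspI fragment must read CGG...CCG")
            if len(self.top_sequence) != len(self.interval) + 2:
                raise ValueError("internal fragment length must be interval length + 2")

    @property
    def insert_length(self) -> int:
        return len(self.top_sequence)


@dataclass(frozen=True, order=True)
class CpGSite:
    """Forward-strand position of the C of a CpG dinucleotide."""

    contig: str
    pos: int


class CytosineContext(str, Enum):
    """Sequence context of a genomic cytosine; H is any base but G."""

    CPG = "CpG"
    CHG = "CHG"
    CHH = "CHH"


def find_mspi_sites(genome: ReferenceGenome) -> list[tuple[str, int]]:
    """Locate every MspI cut on the forward strand.

    Returns (contig, cut) pairs where ``cut`` is the 0-based index of the
    first base of the internal ``CGG`` of each ``CCGG`` occurrence, i.e. the
    position the enzyme cleaves 5' of.  Sorted within each contig; the
    palindromic site means one forward scan covers both strands.
    """
    sites: list[tuple[str, int]] = []
    for name in genome:
        seq = genome[name]
        sites.extend((name, m.start() + 1) for m in _MSPI_RE.finditer(seq))
    return sites


def digest(
    genome: ReferenceGenome,
    cuts: Iterable[tuple[str, int]],
    include_terminal: bool = False,
) -> list[RrbsFragment]:
    """In-silico MspI digestion with end repair.

    Internal fragments span consecutive cuts [p_i, p_j) and carry
    ``genome[p_i:p_j] + "CG"``: the fill-in of the downstream 5'-CG overhang
    duplicates the boundary CpG into both neighbouring fragments.
    Chromosome-terminal pieces (which lack an MspI end and therefore the
    RRBS adaptor structure) are returned only when ``include_terminal``.
    """
    by_contig: dict[str, list[int]] = {}
    for contig, pos in cuts:
        by_contig.setdefault(contig, []).append(pos)

    fragments: list[RrbsFragment] = []
    for name in genome:
        seq = genome[name]
        positions = sorted(by_contig.get(name, []))
        if not positions:
            if include_terminal:
                fragments.append(
                    RrbsFragment(GenomicInterval(name, 0, len(seq)), seq, flanked_both_ends=False)
                )
            continue
        if include_terminal and positions[0] > 0:
            # left terminal piece: repaired CG fill-in at its MspI (right) end
            fragments.append(
                RrbsFragment(
                    GenomicInterval(name, 0, positions[0]),
                    seq[: positions[0]] + "CG",
                    flanked_both_ends=False,
                )
            )
        for p_i, p_j in zip(positions, positions[1:]):
            fragments.append(
                RrbsFragment(GenomicInterval(name, p_i, p_j), seq[p_i:p_j] + "CG")
            )
        if include_terminal and positions[-1] < len(seq):
            fragments.append(
                RrbsFragment(
                    GenomicInterval(name, positions[-1], len(seq)),
                    seq[positions[-1]:],
                    flanked_both_ends=False,
                )
            )
    return fragments


def size_select(
    fragments: Iterable[RrbsFragment],
    min_bp: int = 150,
    max_bp: int = 400,
    adaptor_overhead_bp: int = 65,
) -> list[RrbsFragment]:
    """Gel size selection applied to insert + adaptor length.

    The default window 150-400 bp mirrors the optimal amplification smear;
    ``adaptor_overhead_bp`` defaults to the 65 bp two-step adaptor dimer so
    the window is interpreted as the *ligated* molecule size.  Set the
    overhead to 0 to size-select on the bare insert instead.
    """
    if min_bp < 0 or max_bp < 0 or adaptor_overhead_bp < 0:
        raise ValueError("size-selection bounds must be non-negative")
    if min_bp > max_bp:
        raise ValueError("min_bp must not exceed max_bp")
    return [
        f
        for f in fragments
        if min_bp <= f.insert_length + adaptor_overhead_bp <= max_bp
    ]


def classify_context(
    genome: ReferenceGenome, contig: str, pos: int, strand: str = "+"
) -> CytosineContext:
    """Classify a genomic cytosine as CpG, CHG or CHH on the given strand.

    On the reverse strand the classification runs over the reverse
    complement, i.e. a forward-strand G whose upstream neighbours spell the
    complementary context.  Raises ``ValueError`` if the strand base is not
    C, ``IndexError`` if fewer than two downstream bases exist (callers skip
    such boundary cytosines).  Contexts involving N are never CpG/CHG and
    fall through to CHH only when unambiguous; an N immediately downstream
    raises ``ValueError`` so N-containing contexts can be excluded.
    """
    seq = genome[contig]
    if strand == "+":
        if seq[pos] != "C":
            raise ValueError(f"base at {contig}:{pos}(+) is {seq[pos]}, not C")
        if pos + 2 >= len(seq):
            raise IndexError("fewer than 2 downstream bases")
        nxt, nxt2 = seq[pos + 1], seq[pos + 2]
    elif strand == "-":
        if seq[pos] != "G":
            raise ValueError(f"base at {contig}:{pos}(-) is not C on the reverse strand")
        if pos - 2 < 0:
            raise IndexError("fewer than 2 downstream bases")
        nxt = seq[pos - 1].translate(_COMPLEMENT)
        nxt2 = seq[pos - 2].translate(_COMPLEMENT)
    else:
        raise ValueError(f"invalid strand {strand!r}")
    if "N" in (nxt, nxt2):
        raise ValueError("context contains N")
    if nxt == "G":
        return CytosineContext.CPG
    if nxt2 == "G":
        return CytosineContext.CHG
    return CytosineContext.CHH


def find_cpg_sites(genome: ReferenceGenome) -> list[CpGSite]:
    """Every forward-strand CG dinucleotide, sorted by position.

    Both strands of one CpG map to the same site: reverse-strand calls are
    attributed to the forward C position by the callers.
    """
    sites: list[CpGSite] = []
    for name in genome:
        seq = genome[name]
        start = 0
        while True:
            i = seq.find("CG", start)
            if i < 0:
                break
            sites.append(CpGSite(name, i))
            start = i + 1
    return sites
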