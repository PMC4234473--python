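"""Pre-alignment FASTQ quality control.

Implements the raw-read checks for a directional RRBS library: per-position
base composition, the head/tail cytosine ratio (a conversion check that
should sit near 1), the fraction of reads with GG at positions 2-3 (a
digestion check expected near 100%, alarmed below 95%), per-position mean
phred, and the adaptor-trim / length / quality clean-up stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .reads import BisRead

__all__ = [
    "CompositionMatrix",
    "ReadQcReport",
    "base_composition",
    "c_ratio",
    "gg_start_fraction",
    "phred_summary",
    "trim_and_filter",
    "fastq_qc_report",
]

_BASE_ORDER = "ACGTN"
_BASE_INDEX = {b: i for i, b in enumerate(_BASE_ORDER)}

#: below this GG fraction the MspI digestion is suspect
GG_ALARM_THRESHOLD = 0.95
#: positional mean phred below this raises a quality flag
PHRED_FLAG_THRESHOLD = 30.0


@dataclass
class CompositionMatrix:
    """Per-position base counts; ``counts[p, b]`` for position p (0-based
    internally, reported 1-based) and base b in A,C,G,T,N order.  Column sums
    at position p equal the number of reads of length > p."""

    counts: np.ndarray
    n_reads: int

    @property
    def read_length(self) -> int:
        return self.counts.shape[0]

    def base_fraction(self, base: str) -> np.ndarray:
        totals = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts[:, _BASE_INDEX[base]] / totals, np.nan)


@dataclass
class ReadQcReport:
    composition: CompositionMatrix
    mean_phred_per_position: list[float]
    c_ratio: float
    gg_start_fraction: float
    n_input: int
    n_kept: int
    n_dropped_short: int
    n_dropped_quality: int
    n_trimmed: int
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.n_input == self.n_kept + self.n_dropped_short + self.n_dropped_quality

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_dropped_short": self.n_dropped_short,
            "n_dropped_quality": self.n_dropped_quality,
            "n_trimmed": self.n_trimmed,
            "c_ratio": self.c_ratio,
            "gg_start_fraction": self.gg_start_fraction,
            "mean_phred_per_position": self.mean_phred_per_position,
            "flags": self.flags,
        }


def base_composition(reads: Sequence[BisRead]) -> CompositionMatrix:
    """Exact per-position base tallies; ragged read lengths are allowed."""
    if not reads:
        raise ValueError("base_composition requires at least one read")
    max_len = max(len(r) for r in reads)
    counts = np.zeros((max_len, 5), dtype=np.int64)
    # batch reads of equal length into one matrix per length
    by_len: dict[int, list[str]] = {}
    for r in reads:
        by_len.setdefault(len(r), []).append(r.sequence)
    for length, seqs in by_len.items():
        mat = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), length)
        for bi, base in enumerate(_BASE_ORDER):
            counts[:length, bi] += (mat == ord(base)).sum(axis=0)
    return CompositionMatrix(counts=counts, n_reads=len(reads))


def c_ratio(
    matrix: CompositionMatrix,
    head_range: tuple[int, int] = (1, 10),
    tail_range: tuple[int, int] = (41, 50),
) -> float:
    """Head/tail cytosine-count ratio (1-based inclusive windows).

    In a well-converted library residual cytosines are spread evenly along
    the read, so the ratio sits near 1; an excess in either window points to
    incomplete conversion or position-dependent sequencing error.  Returns
    NaN (with a warning) when the tail window contains no cytosine.
    """
    for lo, hi in (head_range, tail_range):
        if not (1 <= lo <= hi <= matrix.read_length):
            raise ValueError(f"window {(lo, hi)} outside matrix of length {matrix.read_length}")
    ci = _BASE_INDEX["C"]
    head = int(matrix.counts[head_range[0] - 1 : head_range[1], ci].sum())
    tail = int(matrix.counts[tail_range[0] - 1 : tail_range[1], ci].sum())
    if tail == 0:
        warnings.warn("no cytosines in the tail window; C ratio undefined")
        return float("nan")
    return head / tail


def gg_start_fraction(reads: Sequence[BisRead]) -> float:
    """Fraction of reads with G at 1-based positions 2 and 3 (MspI structure)."""
    if not reads:
        return float("nan")
    n = sum(1 for r in reads if len(r) >= 3 and r.sequence[1] == "G" and r.sequence[2] == "G")
    return n / len(reads)


def phred_summary(reads: Sequence[BisRead]) -> list[float]:
    """Arithmetic mean phred per position over the reads covering it."""
    if not reads:
        raise ValueError("phred_summary requires at least one read")
    max_len = max(len(r) for r in reads)
    total = np.zeros(max_len)
    cover = np.zeros(max_len, dtype=np.int64)
    for r in reads:
        q = np.asarray(r.qualities)
        total[: len(q)] += q
        cover[: len(q)] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(cover > 0, total / np.maximum(cover, 1), np.nan)
    return [float(x) for x in means]


def _find_adaptor(sequence: str, adaptor: str) -> int:
    """Leftmost position where the adaptor (or an adaptor prefix running off
    the read end) starts; -1 when absent."""
    full = sequence.find(adaptor)
    limit = full if full >= 0 else len(sequence)
    # partial adaptor at the read end (read-through into the adaptor)
    for pos in range(max(0, len(sequence) - len(adaptor) + 1), limit):
        if pos + len(adaptor) > len(sequence) and sequence[pos:] == adaptor[: len(sequence) - pos]:
            return pos
    return full


def trim_and_filter(
    reads: Iterable[BisRead],
    adaptor: str = "AGATCGGAAGAGC",
    min_length: int = 20,
    min_mean_phred: float = 20.0,
) -> tuple[list[BisRead], dict[str, int]]:
    """Adaptor clipping and read filtering.

    The first occurrence of the adaptor (exact match; a proper adaptor
    prefix is also recognised at the read end) truncates the read at the
    match start.  Reads shorter than ``min_length`` after trimming, or with
    mean phred below ``min_mean_phred``, are dropped.  An empty adaptor
    disables trimming.  Returns the kept reads and exact counters.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    kept: list[BisRead] = []
    counters = {"n_input": 0, "n_kept": 0, "n_dropped_short": 0, "n_dropped_quality": 0, "n_trimmed": 0}
    for r in reads:
        counters["n_input"] += 1
        seq, quals = r.sequence, r.qualities
        if adaptor:
            pos = _find_adaptor(seq, adaptor)
            if pos >= 0:
                seq, quals = seq[:pos], quals[:pos]
                counters["n_trimmed"] += 1
        if len(seq) < min_length:
            counters["n_dropped_short"] += 1
            continue
        mean_q = sum(quals) / len(quals)
        if mean_q < min_mean_phred:
            counters["n_dropped_quality"] += 1
            continue
        counters["n_kept"] += 1
        if len(seq) == len(r.sequence):
            kept.append(r)
        else:
            kept.append(BisRead(r.read_id, seq, list(quals), truth=r.truth))
    return kept, counters


def fastq_qc_report(
    reads: Sequence[BisRead],
    adaptor: str = "",
    min_length: int = 20,
    min_mean_phred: float = 20.0,
    head_range: tuple[int, int] = (1, 10),
    tail_range: tuple[int, int] | None = None,
    gg_alarm: float = GG_ALARM_THRESHOLD,
) -> tuple[list[BisRead], ReadQcReport]:
    """Run the full pre-alignment QC stage and assemble a report.

    The tail window defaults to the last ten positions of the longest kept
    read (the equal-width reading of the head/tail comparison).
    """
    kept, counters = trim_and_filter(reads, adaptor, min_length, min_mean_phred)
    if not kept:
        raise ValueError("no reads survive trimming/filtering")
    comp = base_composition(kept)
    if tail_range is None:
        tail_range = (max(1, comp.read_length - 9), comp.read_length)
    head_range = (head_range[0], min(head_range[1], comp.read_length))
    ratio = c_ratio(comp, head_range, tail_range)
    gg = gg_start_fraction(kept)
    phreds = phred_summary(kept)
    flags = []
    if gg < gg_alarm:
        flags.append(
            f"gg_start_fraction {gg:.3f} below {gg_alarm:.2f}: incomplete MspI digestion?"
        )
    if any(p < PHRED_FLAG_THRESHOLD for p in phreds if not np.isnan(p)):
        flags.append("positional mean phred below 30")
    report = ReadQcReport(
        composition=comp,
        mean_phred_per_position=phreds,
        c_ratio=ratio,
        gg_start_fraction=gg,
        n_input=counters["n_input"],
        n_kept=counters["n_kept"],
        n_dropped_short=counters["n_dropped_short"],
        n_dropped_quality=counters["n_dropped_quality"],
        n_trimmed=counters["n_trimmed"],
        flags=flags,
    )
    return kept, report
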