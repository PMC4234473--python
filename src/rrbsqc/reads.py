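"""Read containers shared by the simulator, QC and aligner."""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import GenomicInterval

__all__ = ["ReadTruth", "BisRead"]


@dataclass(frozen=True)
class ReadTruth:
    """Ground truth attached to a simulated read.

    ``strand`` is the strand of origin (OT = original top, OB = original
    bottom); consumers of reads must never consult it — it exists to score
    aligners and methylation callers.  ``meth_states`` is one character per
    CpG of the source fragment ('M' methylated, 'u' unmethylated), in
    fragment top-strand order.  Positions are 0-based read coordinates.
    """

    fragment: GenomicInterval
    strand: str  # "OT" | "OB"
    molecule: int
    meth_states: str
    failure_positions: tuple[int, ...] = ()
    error_positions: tuple[int, ...] = ()


@dataclass
class BisRead:
    """A single-end bisulfite read with per-base phred qualities."""

    read_id: str
    sequence: str
    qualities: list[int]
    truth: ReadTruth | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities must have equal length")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mean_phred(self) -> float:
        return sum(self.qualities) / len(self.qualities) if self.qualities else float("nan")
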