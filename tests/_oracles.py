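"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the package's seeded/index-based code paths: the
aligner oracle scores every offset on both strands by direct array
comparison, and the string oracles re-derive counts with naive scans.
"""

from __future__ import annotations

import re

import numpy as np

from rrbsqc.genome import ReferenceGenome, revcomp


def naive_mspi_cuts(seq: str) -> list[int]:
    """All CCGG occurrences (overlapping included) via regex lookahead."""
    return [m.start() + 1 for m in re.finditer(r"(?=CCGG)", seq)]


def naive_cpg_count(seq: str) -> int:
    return sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == "CG")


def naive_context(seq: str, pos: int, strand: str) -> str | None:
    """Context of a cytosine by explicit reverse-complement rescan."""
    if strand == "-":
        seq = revcomp(seq)
        pos = len(seq) - 1 - pos
    if seq[pos] != "C" or pos + 2 >= len(seq):
        return None
    if "N" in seq[pos + 1 : pos + 3]:
        return None
    if seq[pos + 1] == "G":
        return "CpG"
    if seq[pos + 2] == "G":
        return "CHG"
    return "CHH"


class BruteForceAligner:
    """Score a read at every offset of both reduced strands.

    Mismatches are counted in three-letter space (read and reference both
    C->T collapsed), exactly mirroring the directional protocol.  Status
    semantics match best-unique: a single minimal-mismatch (space, offset)
    within the budget is unique; several are ambiguous (ties across strands
    included); none within budget is unaligned.
    """

    def __init__(self, genome: ReferenceGenome):
        self.genome = genome
        self.fwd: dict[str, np.ndarray] = {}
        self.rev: dict[str, np.ndarray] = {}
        for name in genome:
            seq = genome[name]
            self.fwd[name] = np.frombuffer(seq.replace("C", "T").encode(), np.uint8)
            self.rev[name] = np.frombuffer(
                revcomp(seq).replace("C", "T").encode(), np.uint8
            )

    def align_batch(
        self, sequences: list[str], max_mismatch: int = 2
    ) -> list[tuple[str, tuple[str, str, int] | None, int | None]]:
        """Returns (status, (contig, space, start) or None, mismatches or None)."""
        by_len: dict[int, list[int]] = {}
        for i, s in enumerate(sequences):
            by_len.setdefault(len(s), []).append(i)
        results: list = [None] * len(sequences)
        for L, idxs in by_len.items():
            reduced = np.frombuffer(
                "".join(sequences[i].replace("C", "T") for i in idxs).encode(), np.uint8
            ).reshape(len(idxs), L)
            # best and runner-up mismatch count per read across all placements
            best = np.full(len(idxs), np.iinfo(np.int32).max, dtype=np.int64)
            best_hit: list[tuple[str, str, int] | None] = [None] * len(idxs)
            n_best = np.zeros(len(idxs), dtype=np.int64)
            for contig in self.genome:
                for space, text in (("fwd", self.fwd[contig]), ("rev", self.rev[contig])):
                    n_off = len(text) - L + 1
                    if n_off <= 0:
                        continue
                    mm = np.zeros((len(idxs), n_off), dtype=np.int16)
                    for i in range(L):
                        mm += reduced[:, i : i + 1] != text[np.newaxis, i : i + n_off]
                    row_min = mm.min(axis=1)
                    for r in range(len(idxs)):
                        if row_min[r] < best[r]:
                            best[r] = row_min[r]
                            hits = np.nonzero(mm[r] == row_min[r])[0]
                            n_best[r] = len(hits)
                            best_hit[r] = (contig, space, int(hits[0]))
                        elif row_min[r] == best[r]:
                            n_best[r] += int((mm[r] == row_min[r]).sum())
            for k, i in enumerate(idxs):
                if best[k] > max_mismatch:
                    results[i] = ("unaligned", None, None)
                elif n_best[k] > 1:
                    results[i] = ("ambiguous", None, None)
                else:
                    results[i] = ("unique", best_hit[k], int(best[k]))
        return results


def oracle_placement_to_interval(
    genome: ReferenceGenome, hit: tuple[str, str, int], read_len: int
) -> tuple[str, int, int, str]:
    contig, space, start = hit
    if space == "fwd":
        return (contig, start, start + read_len, "+")
    clen = genome.length(contig)
    return (contig, clen - start - read_len, clen - start, "-")
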