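"""Post-alignment methylation QC.

Covers the conversion-rate estimate (converted fraction of CHH+CHG calls —
non-CpG methylation is negligible in mammals, so residual non-CpG cytosines
measure bisulfite failure), per-CpG methylation summaries and their
histograms, coverage statistics with and without PCR duplicates, and the
duplicate-representativeness test: at a high-coverage locus with several
differentially methylated CpGs, the per-CpG methylation frequencies of the
deduplicated read pool and the full pool should correlate strongly; a weak
correlation flags PCR amplification bias, in which case duplicates should
not be used for coverage statistics.

In RRBS most reads at a locus share their MspI-defined 5' end, so
"duplicate" is keyed on (contig, 5' position, strand, read sequence): reads
with identical coordinates but different methylation patterns or sequencing
errors are genuinely independent molecules and stay in the unique pool.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .align import AlignedRead, AlignStatus, MethylationCall
from .genome import CpGSite, CytosineContext, GenomicInterval

__all__ = [
    "CpGSummary",
    "CoverageReport",
    "DupTestResult",
    "conversion_rate",
    "deduplicate",
    "cpg_summaries",
    "cpg_summaries_from_calls",
    "coverage_report",
    "methylation_histogram",
    "coverage_log_histogram",
    "select_test_loci",
    "duplicate_representativeness",
    "read_key",
    "locus_key",
]

DedupMode = Literal["unique_only", "all_reads"]


@dataclass(frozen=True)
class CpGSummary:
    site: CpGSite
    n_methylated: int
    n_total: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_methylated <= self.n_total:
            raise ValueError("need 0 <= n_methylated <= n_total")

    @property
    def frequency(self) -> float:
        if self.n_total == 0:
            return float("nan")
        return self.n_methylated / self.n_total


@dataclass(frozen=True)
class CoverageReport:
    n_cpgs_1x: int
    n_cpgs_5x: int
    n_cpgs_10x: int
    mean_coverage: float
    dedup_mode: DedupMode


@dataclass(frozen=True)
class DupTestResult:
    locus: GenomicInterval
    n_unique_reads: int
    n_all_reads: int
    unique_frequencies: tuple[float, ...]
    all_frequencies: tuple[float, ...]
    r_squared: float
    p_value: float
    degenerate: bool = False  # zero variance in a pool: r undefined

    @property
    def n_sites(self) -> int:
        return len(self.unique_frequencies)


def conversion_rate(calls: Iterable[MethylationCall]) -> float:
    """Bisulfite conversion percentage from non-CpG (CHH+CHG) calls.

    100 x converted / total over CHH and CHG contexts; CpG calls are
    excluded because genuine CpG methylation would deflate the estimate.
    NaN with a warning when no non-CpG call exists.
    """
    n_total = 0
    n_conv = 0
    for c in calls:
        if c.context is CytosineContext.CPG:
            continue
        n_total += 1
        n_conv += not c.methylated
    if n_total == 0:
        warnings.warn("no CHH/CHG calls: conversion rate undefined")
        return float("nan")
    return 100.0 * n_conv / n_total


def read_key(aligned: AlignedRead) -> tuple[str, int, str, str]:
    """Duplicate key: contig, 5' position, strand, full read sequence."""
    iv = aligned.placement
    five_prime = iv.start if iv.strand == "+" else iv.end
    return (iv.contig, five_prime, iv.strand, aligned.read.sequence)


def locus_key(aligned: AlignedRead) -> tuple[str, int, str]:
    """Read-stack key: the MspI-defined 5' end and strand."""
    return read_key(aligned)[:3]


def deduplicate(
    aligned_reads: Sequence[AlignedRead],
) -> tuple[list[AlignedRead], dict[tuple, int]]:
    """One representative per duplicate key, plus the multiplicity map.

    Only unique-status alignments are accepted.  Multiplicities sum to the
    input size; reads at the same position whose sequences differ (distinct
    methylation patterns or errors) are kept as independent observations.
    """
    reps: dict[tuple, AlignedRead] = {}
    mult: dict[tuple, int] = {}
    for a in aligned_reads:
        if a.status is not AlignStatus.UNIQUE:
            raise ValueError("deduplicate expects unique alignments only")
        k = read_key(a)
        mult[k] = mult.get(k, 0) + 1
        reps.setdefault(k, a)
    return list(reps.values()), mult


def cpg_summaries_from_calls(calls: Iterable[MethylationCall]) -> list[CpGSummary]:
    """Per-site tallies over CpG-context calls only, sorted by site."""
    meth: dict[CpGSite, int] = {}
    total: dict[CpGSite, int] = {}
    for c in calls:
        if c.context is not CytosineContext.CPG:
            continue
        total[c.site] = total.get(c.site, 0) + 1
        if c.methylated:
            meth[c.site] = meth.get(c.site, 0) + 1
    return [
        CpGSummary(site=s, n_methylated=meth.get(s, 0), n_total=t)
        for s, t in sorted(total.items())
    ]


def cpg_summaries(
    aligned_reads: Sequence[AlignedRead], dedup_mode: DedupMode = "all_reads"
) -> list[CpGSummary]:
    """Per-CpG methylated/total counts from unique alignments.

    ``unique_only`` first collapses PCR duplicates; ``all_reads`` counts
    every read (the coverage-inflating but often necessary choice in RRBS).
    """
    if dedup_mode == "unique_only":
        pool, _ = deduplicate(aligned_reads)
    elif dedup_mode == "all_reads":
        pool = list(aligned_reads)
    else:
        raise ValueError(f"unknown dedup_mode {dedup_mode!r}")
    calls = [c for a in pool for c in a.calls]
    return cpg_summaries_from_calls(calls)


def coverage_report(
    summaries: Sequence[CpGSummary], dedup_mode: DedupMode = "all_reads"
) -> CoverageReport:
    """CpG counts at >=1X/5X/10X and mean coverage over covered CpGs."""
    if not summaries:
        warnings.warn("no covered CpGs: empty coverage report")
        return CoverageReport(0, 0, 0, 0.0, dedup_mode)
    cov = np.array([s.n_total for s in summaries])
    covered = cov[cov >= 1]
    return CoverageReport(
        n_cpgs_1x=int((cov >= 1).sum()),
        n_cpgs_5x=int((cov >= 5).sum()),
        n_cpgs_10x=int((cov >= 10).sum()),
        mean_coverage=float(covered.mean()) if covered.size else 0.0,
        dedup_mode=dedup_mode,
    )


def methylation_histogram(
    summaries: Sequence[CpGSummary], bin_width_pct: float = 5.0
) -> np.ndarray:
    """Histogram of per-CpG methylation percentages in ``bin_width_pct`` bins.

    Bins are [0,w), [w,2w), ..., with the last bin closed at 100 so fully
    methylated CpGs are counted; counts sum to the number of summarised CpGs.
    """
    n_bins = int(round(100.0 / bin_width_pct))
    counts = np.zeros(n_bins, dtype=np.int64)
    for s in summaries:
        if s.n_total == 0:
            continue
        pct = 100.0 * s.frequency
        b = min(int(pct // bin_width_pct), n_bins - 1)
        counts[b] += 1
    return counts


def coverage_log_histogram(
    summaries: Sequence[CpGSummary], bin_width: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of log10 coverage (so 1.0 on the axis means 10X).

    Returns (bin_left_edges, counts); only CpGs with coverage >= 1 enter,
    and counts are conserved.
    """
    logs = [math.log10(s.n_total) for s in summaries if s.n_total >= 1]
    if not logs:
        return np.zeros(0), np.zeros(0, dtype=np.int64)
    idx = [int(math.floor(v / bin_width + 1e-9)) for v in logs]
    n_bins = max(idx) + 1
    counts = np.zeros(n_bins, dtype=np.int64)
    for i in idx:
        counts[i] += 1
    edges = np.arange(n_bins) * bin_width
    return edges, counts


def _stack_frequencies(
    stack: Sequence[AlignedRead],
) -> dict[CpGSite, tuple[int, int]]:
    """site -> (n_methylated, n_total) over CpG calls of a read stack."""
    out: dict[CpGSite, tuple[int, int]] = {}
    for a in stack:
        for c in a.calls:
            if c.context is not CytosineContext.CPG:
                continue
            m, t = out.get(c.site, (0, 0))
            out[c.site] = (m + c.methylated, t + 1)
    return out


def select_test_loci(
    aligned_reads: Sequence[AlignedRead],
    min_unique_reads: int = 11,
    min_diff_cpgs: int = 4,
) -> list[list[AlignedRead]]:
    """Read stacks suitable for the duplicate-representativeness test.

    A locus is one MspI-defined read stack (same contig, 5' end, strand).
    Kept are stacks with at least ``min_unique_reads`` deduplicated reads
    and at least ``min_diff_cpgs`` CpGs whose unique-pool methylation
    frequency is strictly between 0 and 1 (differentially methylated within
    the stack — without those the test has no variance to correlate).
    """
    stacks: dict[tuple, list[AlignedRead]] = {}
    for a in aligned_reads:
        if a.status is not AlignStatus.UNIQUE:
            continue
        stacks.setdefault(locus_key(a), []).append(a)
    selected = []
    for key in sorted(stacks):
        stack = stacks[key]
        uniq, _ = deduplicate(stack)
        if len(uniq) < min_unique_reads:
            continue
        freqs = _stack_frequencies(uniq)
        n_diff = sum(1 for m, t in freqs.values() if 0 < m < t)
        if n_diff >= min_diff_cpgs:
            selected.append(stack)
    return selected


def duplicate_representativeness(
    locus_reads: Sequence[AlignedRead] | None = None,
    unique_frequencies: Sequence[float] | None = None,
    all_frequencies: Sequence[float] | None = None,
    locus: GenomicInterval | None = None,
    n_unique_reads: int = 0,
    n_all_reads: int = 0,
) -> DupTestResult:
    """Pearson correlation of per-CpG methylation between read pools.

    Either pass a stack of aligned reads at one locus (the pools are formed
    by deduplication) or the two frequency vectors directly.  Reports r² and
    the two-sided p-value from t = r*sqrt(n-2)/sqrt(1-r²) on n-2 degrees of
    freedom.  Requires at least 3 paired sites; zero variance in either
    vector yields a degenerate (NaN) result rather than an exception.
    """
    if locus_reads is not None:
        uniq, _ = deduplicate(list(locus_reads))
        fu = _stack_frequencies(uniq)
        fa = _stack_frequencies(list(locus_reads))
        sites = sorted(set(fu) & set(fa))
        unique_frequencies = [fu[s][0] / fu[s][1] for s in sites]
        all_frequencies = [fa[s][0] / fa[s][1] for s in sites]
        n_unique_reads, n_all_reads = len(uniq), len(locus_reads)
        if locus is None and locus_reads:
            ivs = [a.placement for a in locus_reads]
            locus = GenomicInterval(
                ivs[0].contig,
                min(iv.start for iv in ivs),
                max(iv.end for iv in ivs),
                ivs[0].strand,
            )
    if unique_frequencies is None or all_frequencies is None:
        raise ValueError("provide locus reads or both frequency vectors")
    u = np.asarray(unique_frequencies, dtype=float)
    a = np.asarray(all_frequencies, dtype=float)
    if u.shape != a.shape or u.size < 3:
        raise ValueError("need >= 3 paired per-CpG frequencies")
    if locus is None:
        locus = GenomicInterval("NA", 0, 1)
    if np.ptp(u) == 0 or np.ptp(a) == 0:
        warnings.warn("zero variance in a frequency vector: r undefined")
        return DupTestResult(
            locus, n_unique_reads, n_all_reads, tuple(u), tuple(a),
            float("nan"), float("nan"), degenerate=True,
        )
    r, p = stats.pearsonr(u, a)
    return DupTestResult(
        locus=locus,
        n_unique_reads=n_unique_reads,
        n_all_reads=n_all_reads,
        unique_frequencies=tuple(u),
        all_frequencies=tuple(a),
        r_squared=float(r * r),
        p_value=float(p),
    )
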