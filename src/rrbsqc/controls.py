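"""Region-level controls, pooling design math, and oligo utilities.

Three kinds of built-in sanity checks for an RRBS experiment:

* **Positive controls** — imprinted CpG islands carry parent-of-origin
  monoallelic methylation and should sit near a characteristic mid-range
  level; unmethylated housekeeping islands (GAPDH, ACTB) should stay near
  zero.  Reference expectations for adult human brain are bundled
  (``load_control_regions``); they are tissue-specific, so other tissues
  need their own table.
* **Negative control** — the mammalian mitochondrial genome is unmethylated,
  so every cytosine aligned to the MT contig should read T; the residual C
  fraction over *all* contexts (CpG included) estimates conversion failure,
  and any apparent CpG methylation above a small threshold flags a problem.
* **Lane design** — RRBS reads all start CGG/TGG, starving the sequencer of
  base diversity at the first positions; pooling a fraction of
  non-bisulfite DNA restores it.  ``lane_fractions`` gives the per-library
  share of an equimolar pool, ``first_bases_diversity`` the per-position
  Shannon entropy the spike-in is meant to raise.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .align import MethylationCall
from .genome import CytosineContext, GenomicInterval
from .methqc import CpGSummary, conversion_rate
from .reads import BisRead

__all__ = [
    "ControlRegion",
    "RegionSummary",
    "LaneDesign",
    "MtControlReport",
    "load_control_regions",
    "region_summary",
    "control_check",
    "mt_negative_control",
    "lane_fractions",
    "first_bases_diversity",
    "load_oligos",
    "clean_oligo",
    "oligo_length",
    "adaptor_dimer_length",
    "extract_index",
]

_INDEX_FLANK_5 = "CAAGCAGAAGACGGCATACGAGAT"
_INDEX_FLANK_3 = "GTGACTGGAGTTC"


@dataclass(frozen=True)
class ControlRegion:
    name: str
    interval: GenomicInterval
    expected_mean_pct: float
    expected_sd_pct: float
    polarity: str  # "imprinted_mid" | "unmethylated_low"

    def __post_init__(self) -> None:
        if self.expected_sd_pct < 0:
            raise ValueError("expected_sd_pct must be >= 0")
        if not 0 <= self.expected_mean_pct <= 100:
            raise ValueError("expected_mean_pct must be a percentage")


@dataclass(frozen=True)
class RegionSummary:
    name: str
    pct_methylation: float
    n_cpgs_covered: int
    mean_cov_per_cpg: float
    pass_flag: bool = True
    message: str = ""


@dataclass(frozen=True)
class LaneDesign:
    n_bis_libraries: int
    spike_in_fraction: float

    def __post_init__(self) -> None:
        if self.n_bis_libraries < 1:
            raise ValueError("need at least one bisulfite library")
        if not 0 <= self.spike_in_fraction < 1:
            raise ValueError("spike_in_fraction must be in [0,1)")


@dataclass(frozen=True)
class MtControlReport:
    conversion_rate_pct: float
    cpg_methylated_pct: float
    n_calls: int
    flagged: bool
    message: str = ""


def load_control_regions(path=None) -> tuple[list[ControlRegion], "object"]:
    """Load a control-region table (bundled brain reference by default).

    Returns (regions, table) where ``table`` is the full pandas DataFrame
    including the per-subject percentage columns, for users who want the
    underlying reference data.
    """
    import pandas as pd

    if path is None:
        path = importlib.resources.files("rrbsqc.data") / "imprinted_regions.tsv"
    table = pd.read_csv(str(path), sep="\t", comment="#")
    regions = [
        ControlRegion(
            name=row["gene"],
            interval=GenomicInterval(row["contig"], int(row["start"]), int(row["end"])),
            expected_mean_pct=float(row["expected_mean_pct"]),
            expected_sd_pct=float(row["expected_sd_pct"]),
            polarity=row["polarity"],
        )
        for _, row in table.iterrows()
    ]
    return regions, table


def region_summary(
    summaries: Sequence[CpGSummary], region: ControlRegion | GenomicInterval, name: str | None = None
) -> RegionSummary:
    """Coverage-weighted percent methylation over the CpGs of a region.

    pct = 100 * sum(n_methylated) / sum(n_total) over covered CpGs inside
    the interval (so deeply covered CpGs weigh more, matching how calls
    accumulate); an unweighted per-CpG mean is available via
    ``weighted=False`` in ``region_percent``.
    """
    if isinstance(region, ControlRegion):
        iv, rname = region.interval, region.name
    else:
        iv, rname = region, name or "region"
    inside = [s for s in summaries if iv.contains(s.site.contig, s.site.pos) and s.n_total > 0]
    if not inside:
        return RegionSummary(
            name=rname,
            pct_methylation=float("nan"),
            n_cpgs_covered=0,
            mean_cov_per_cpg=0.0,
            pass_flag=False,
            message="no covered CpG in region",
        )
    meth = sum(s.n_methylated for s in inside)
    total = sum(s.n_total for s in inside)
    return RegionSummary(
        name=rname,
        pct_methylation=100.0 * meth / total,
        n_cpgs_covered=len(inside),
        mean_cov_per_cpg=total / len(inside),
    )


def region_percent(summaries: Sequence[CpGSummary], iv: GenomicInterval, weighted: bool = True) -> float:
    """Percent methylation of a region; unweighted averages per-CpG frequencies."""
    inside = [s for s in summaries if iv.contains(s.site.contig, s.site.pos) and s.n_total > 0]
    if not inside:
        return float("nan")
    if weighted:
        return 100.0 * sum(s.n_methylated for s in inside) / sum(s.n_total for s in inside)
    return 100.0 * sum(s.frequency for s in inside) / len(inside)


def control_check(
    summary: RegionSummary,
    region: ControlRegion,
    k_sd: float = 3.0,
    floor_sd_pct: float = 1.0,
    unmethylated_ceiling_pct: float = 5.0,
) -> RegionSummary:
    """Pass/flag a region against its reference expectation.

    Pass iff |observed - expected| <= k_sd * max(SD, floor); the SD floor
    stops tiny published SDs from flagging ordinary sampling noise.
    Unmethylated control regions must additionally stay below the ceiling.
    """
    if math.isnan(summary.pct_methylation):
        return summary
    band = k_sd * max(region.expected_sd_pct, floor_sd_pct)
    dev = abs(summary.pct_methylation - region.expected_mean_pct)
    ok = dev <= band
    msg = ""
    if not ok:
        msg = (
            f"{region.name}: observed {summary.pct_methylation:.1f}% deviates "
            f"{dev:.1f} pp from expected {region.expected_mean_pct:.1f}% "
            f"(> {k_sd:.0f} x SD band {band:.1f} pp)"
        )
    if region.polarity == "unmethylated_low" and summary.pct_methylation > unmethylated_ceiling_pct:
        ok = False
        msg = (
            f"{region.name}: unmethylated control at "
            f"{summary.pct_methylation:.1f}% exceeds {unmethylated_ceiling_pct:.1f}% ceiling"
        )
    return RegionSummary(
        name=summary.name,
        pct_methylation=summary.pct_methylation,
        n_cpgs_covered=summary.n_cpgs_covered,
        mean_cov_per_cpg=summary.mean_cov_per_cpg,
        pass_flag=ok,
        message=msg,
    )


def mt_negative_control(
    calls: Iterable[MethylationCall],
    mt_contig: str = "chrM",
    cpg_flag_threshold_pct: float = 2.0,
) -> MtControlReport:
    """Conversion check on the (unmethylated) mitochondrial contig.

    Unlike the genome-wide estimator, this uses *all* contexts including
    CpG, because no cytosine on the MT genome is methylated.  Flags when the
    apparent CpG-context methylation exceeds the threshold.
    """
    mt_calls = [c for c in calls if c.site.contig == mt_contig]
    if not mt_calls:
        warnings.warn(f"no calls on MT contig {mt_contig!r}")
        return MtControlReport(
            float("nan"), float("nan"), 0, False, "no MT alignments"
        )
    n = len(mt_calls)
    conv = 100.0 * sum(not c.methylated for c in mt_calls) / n
    cpg = [c for c in mt_calls if c.context is CytosineContext.CPG]
    cpg_pct = (
        100.0 * sum(c.methylated for c in cpg) / len(cpg) if cpg else float("nan")
    )
    flagged = (not math.isnan(cpg_pct)) and cpg_pct > cpg_flag_threshold_pct
    msg = (
        f"apparent MT CpG methylation {cpg_pct:.2f}% exceeds "
        f"{cpg_flag_threshold_pct:.1f}%"
        if flagged
        else ""
    )
    return MtControlReport(conv, cpg_pct, n, flagged, msg)


def lane_fractions(design: LaneDesign) -> float:
    """Percent of the lane taken by each bisulfite library (equimolar pool)."""
    return 100.0 * (1.0 - design.spike_in_fraction) / design.n_bis_libraries


def first_bases_diversity(reads: Sequence[BisRead], n_positions: int = 3) -> list[float]:
    """Per-position Shannon entropy (bits) over {A,C,G,T} at the read start.

    Zero at a monomorphic position, 2 bits at a uniformly random one; MspI
    RRBS reads have ~0 at positions 2-3 (the GG), which is what a spike-in
    of non-bisulfite DNA is designed to mitigate.
    """
    entropies = []
    for p in range(n_positions):
        counts = Counter(r.sequence[p] for r in reads if len(r) > p and r.sequence[p] in "ACGT")
        total = sum(counts.values())
        if total == 0:
            entropies.append(float("nan"))
            continue
        h = -sum(
            (c / total) * math.log2(c / total) for c in counts.values() if c > 0
        )
        entropies.append(h)
    return entropies


# ---------------------------------------------------------------------------
# Oligo utilities


def load_oligos(path=None) -> dict[str, str]:
    """Bundled two-step adaptor/primer table: name -> annotated sequence."""
    if path is None:
        path = importlib.resources.files("rrbsqc.data") / "oligos.tsv"
    oligos: dict[str, str] = {}
    with open(str(path)) as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True  # column header row
                continue
            name, seq = line.split("\t")
            oligos[name] = seq
    return oligos


def clean_oligo(seq: str) -> str:
    """Strip annotation (bold markers, asterisks, p-/-OH, phosphorothioate s)."""
    s = seq.strip()
    if s.startswith("p-"):
        s = s[2:]
    if s.endswith("-OH"):
        s = s[:-3]
    return "".join(ch for ch in s if ch in "ACGT")


def oligo_length(seq: str) -> int:
    """Nucleotide count of an annotated oligo."""
    return len(clean_oligo(seq))


def adaptor_dimer_length(oligos: Mapping[str, str], a: str = "mC-PE1", b: str = "mC-PE2") -> int:
    """Length of the adaptor-dimer amplicon (sum of the two adaptor oligos)."""
    return oligo_length(oligos[a]) + oligo_length(oligos[b])


def extract_index(seq: str) -> str:
    """The 6-nt index between the constant flanks of an indexing primer."""
    clean = clean_oligo(seq)
    i = clean.find(_INDEX_FLANK_5)
    j = clean.find(_INDEX_FLANK_3)
    if i < 0 or j < 0 or j <= i:
        raise ValueError("index flanks not found in oligo")
    index = clean[i + len(_INDEX_FLANK_5) : j]
    if len(index) != 6:
        raise ValueError(f"expected a 6-nt index, got {index!r}")
    return index
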