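"""Directional RRBS read simulator with ground truth.

The molecular model: an end-repaired MspI fragment is adaptor-ligated,
bisulfite-converted, PCR-amplified and sequenced for 50 cycles from either
the original top (OT) or original bottom (OB) strand.  Because both strands
start at an MspI end, every simulated read begins ``CGG`` (methylated start
CpG) or ``TGG`` (converted), exactly like a real directional RRBS library.

Per molecule: CpG methylation states are Bernoulli draws from the methylome,
every unmethylated/non-CpG cytosine on the sequenced strand deaminates to T
except with probability ``conversion_failure`` (the bisulfite failure rate),
PCR emits a geometric number of copies — optionally tilted toward short or
cytosine-poor molecules to reproduce amplification bias — and each copy then
acquires independent sequencing errors.

The default methylome is the bimodal brain profile (most CpGs <5% or >95%
methylated, with a small bump at 45-50%); CpGs at the MspI cut sites
themselves default to a strongly hypomethylated profile because CCGG sites
concentrate in hypomethylated CpG islands (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome import (
    CpGSite,
    GenomicInterval,
    ReferenceGenome,
    RrbsFragment,
    digest,
    find_cpg_sites,
    find_mspi_sites,
    revcomp,
    size_select,
)
from .io import write_fastq
from .reads import BisRead, ReadTruth

__all__ = [
    "MethylomeProfile",
    "Methylome",
    "SimConfig",
    "SimResult",
    "DEFAULT_FLANK_PROFILE",
    "RRBS_GENOME_BASE_PROBS",
    "random_genome",
    "rrbs_target_genome",
    "sample_methylome",
    "simulate_reads",
    "simulate_library",
    "write_fastq",
    "write_truth_tsv",
    "write_methylome_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_C, _G, _T = ord("C"), ord("G"), ord("T")


@dataclass(frozen=True)
class MethylomeProfile:
    """Mixture defining the per-CpG methylation-level distribution.

    With probability ``frac_low`` a level is uniform on [0, low_max), with
    ``frac_high`` uniform on (high_min, 1], with ``mid_bump_weight`` uniform
    on [0.45, 0.50) (the reproducible excess seen in brain methylomes), and
    otherwise uniform on [low_max, high_min].
    """

    frac_low: float = 0.60
    frac_high: float = 0.275
    low_max: float = 0.05
    high_min: float = 0.95
    mid_bump_weight: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("frac_low", "frac_high", "mid_bump_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.frac_low + self.frac_high + self.mid_bump_weight > 1.0 + 1e-12:
            raise ValueError("mixture weights exceed 1")
        if not 0.0 < self.low_max < self.high_min < 1.0:
            raise ValueError("need 0 < low_max < high_min < 1")

    @property
    def mean_level(self) -> float:
        """Expected methylation level under the mixture."""
        rest = 1.0 - self.frac_low - self.frac_high - self.mid_bump_weight
        return (
            self.frac_low * self.low_max / 2
            + self.frac_high * (1 + self.high_min) / 2
            + self.mid_bump_weight * 0.475
            + rest * (self.low_max + self.high_min) / 2
        )


#: MspI-flank CpGs sit overwhelmingly in hypomethylated CpG islands.
DEFAULT_FLANK_PROFILE = MethylomeProfile(
    frac_low=0.95, frac_high=0.04, mid_bump_weight=0.0
)


class Methylome:
    """Map from CpGSite to a methylation probability in [0,1]."""

    def __init__(self, levels: Mapping[CpGSite, float]):
        for site, m in levels.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"level {m} at {site} outside [0,1]")
        self._levels = dict(levels)

    @property
    def levels(self) -> dict[CpGSite, float]:
        return dict(self._levels)

    def __getitem__(self, site: CpGSite) -> float:
        return self._levels[site]

    def get(self, site: CpGSite, default: float = 0.0) -> float:
        return self._levels.get(site, default)

    def __contains__(self, site: CpGSite) -> bool:
        return site in self._levels

    def __len__(self) -> int:
        return len(self._levels)

    def __iter__(self):
        return iter(self._levels)

    def with_levels(self, overrides: Mapping[CpGSite, float]) -> "Methylome":
        merged = dict(self._levels)
        merged.update(overrides)
        return Methylome(merged)


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    depth is the mean number of independent molecules per fragment (before
    PCR duplication); dup_geometric_p is the success parameter of the
    geometric copy-number law (mean copies per molecule = 1/p when
    unbiased); dup_length_bias / dup_c_bias tilt the duplication probability
    by exp(-a*(len-150)/250 - b*nC) so that, when positive, short and
    cytosine-poor molecules over-amplify — the PCR failure mode the
    duplicate-representativeness test is designed to catch.
    """

    read_length: int = 50
    conversion_failure: float = 0.01
    seq_error_rate: float = 0.0002
    ot_fraction: float = 0.5
    depth: float = 20.0
    dup_geometric_p: float = 0.5
    dup_length_bias: float = 0.0
    dup_c_bias: float = 0.0
    base_quality: int = 37
    quality_decay: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for name in ("conversion_failure", "seq_error_rate", "ot_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if not 0.0 < self.dup_geometric_p <= 1.0:
            raise ValueError("dup_geometric_p must be in (0,1]")


@dataclass
class SimResult:
    """Everything an end-to-end QC run needs, with ground truth."""

    genome: ReferenceGenome
    fragments: list[RrbsFragment]
    methylome: Methylome
    reads: list[BisRead]


def random_genome(
    length: int,
    seed: int = 0,
    base_probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    name: str = "sim1",
) -> ReferenceGenome:
    """I.i.d. random contig over ACGT (probabilities in A,C,G,T order)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    p = np.asarray(base_probs, dtype=float)
    if p.shape != (4,) or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("base_probs must be 4 non-negative values summing to 1")
    rng = np.random.default_rng(seed)
    seq = _BASES[rng.choice(4, size=length, p=p)].tobytes().decode()
    return ReferenceGenome({name: seq})


#: A,C,G,T probabilities emulating the GC-rich, CpG-island-enriched sequence
#: space that MspI digestion actually samples (RRBS covers ~2.5% of a mammalian
#: genome, heavily weighted toward CpG islands at ~60% GC).
RRBS_GENOME_BASE_PROBS = (0.20, 0.30, 0.30, 0.20)


def rrbs_target_genome(length: int, seed: int = 0, name: str = "sim1") -> ReferenceGenome:
    """Random genome with RRBS-target-like (GC-rich) base composition.

    Compared to a uniform-composition genome this yields realistically dense
    MspI sites and interior CpGs, which also stabilises composition-based QC
    statistics at desk scale (many more fragments per 100 kb).
    """
    return random_genome(length, seed=seed, base_probs=RRBS_GENOME_BASE_PROBS, name=name)


def sample_methylome(
    sites: Sequence[CpGSite],
    profile: MethylomeProfile = MethylomeProfile(),
    rng: np.random.Generator | None = None,
) -> Methylome:
    """Assign each CpG an independent level from the mixture profile."""
    if not sites:
        raise ValueError("no CpG sites to assign levels to")
    if rng is None:
        rng = np.random.default_rng(profile.seed)
    n = len(sites)
    u = rng.random(n)
    v = rng.random(n)
    levels = np.empty(n)
    c1 = profile.frac_low
    c2 = c1 + profile.frac_high
    c3 = c2 + profile.mid_bump_weight
    low = u < c1
    high = (u >= c1) & (u < c2)
    mid = (u >= c2) & (u < c3)
    rest = u >= c3
    levels[low] = v[low] * profile.low_max
    levels[high] = 1.0 - v[high] * (1.0 - profile.high_min)  # (high_min, 1]
    levels[mid] = 0.45 + v[mid] * 0.05
    levels[rest] = profile.low_max + v[rest] * (profile.high_min - profile.low_max)
    return Methylome({s: float(m) for s, m in zip(sites, levels)})


def _fragment_cpg_index(frag: RrbsFragment) -> tuple[np.ndarray, list[CpGSite]]:
    """Positions (fragment top-strand coords) and genomic sites of fragment CpGs.

    The end-repaired top sequence of an internal fragment equals
    genome[start:end+2], so fragment coordinate j maps to genomic start+j.
    """
    seq = frag.top_sequence
    pos = []
    j = seq.find("CG")
    while j >= 0:
        pos.append(j)
        j = seq.find("CG", j + 1)
    sites = [CpGSite(frag.interval.contig, frag.interval.start + j) for j in pos]
    return np.asarray(pos, dtype=np.int64), sites


def _apply_sequencing_errors(
    reads: np.ndarray, rate: float, rng: np.random.Generator
) -> list[tuple[int, ...]]:
    """Substitute a uniformly chosen *different* base per position with prob rate."""
    if rate <= 0 or reads.size == 0:
        return [()] * reads.shape[0]
    mask = rng.random(reads.shape) < rate
    rows, cols = np.nonzero(mask)
    if rows.size:
        code = np.searchsorted(_BASES, reads[rows, cols])
        shift = rng.integers(1, 4, size=rows.size)
        reads[rows, cols] = _BASES[(code + shift) % 4]
    out: list[tuple[int, ...]] = [()] * reads.shape[0]
    for r, c in zip(rows.tolist(), cols.tolist()):
        out[r] = out[r] + (c,)
    return out


def simulate_reads(
    fragments: Sequence[RrbsFragment],
    methylome: Methylome,
    cfg: SimConfig = SimConfig(),
    rng: np.random.Generator | None = None,
) -> list[BisRead]:
    """Simulate directional single-end bisulfite reads with attached truth.

    Reads are the first ``read_length`` bases of the converted OT strand, or
    of the converted OB strand (the reverse complement, which also starts at
    an MspI end).  Fragments shorter than the read length yield truncated
    reads, never padded ones.  All randomness flows from ``cfg.seed`` (or an
    explicitly supplied generator), so identical configurations give
    byte-identical output.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    L = cfg.read_length
    eps = cfg.conversion_failure
    reads_out: list[BisRead] = []
    mol_counter = 0

    for frag in fragments:
        m = len(frag.top_sequence)
        Lp = min(L, m)
        n_mol = int(rng.poisson(cfg.depth))
        if n_mol == 0:
            continue
        cpg_pos, cpg_sites = _fragment_cpg_index(frag)
        levels = np.array([methylome.get(s, 0.0) for s in cpg_sites])
        n_cpg = len(cpg_pos)
        # per-molecule methylation states (shared by both strands and all copies)
        states = rng.random((n_mol, n_cpg)) < levels if n_cpg else np.zeros((n_mol, 0), bool)
        is_ot = rng.random(n_mol) < cfg.ot_fraction

        top = np.frombuffer(frag.top_sequence.encode(), dtype=np.uint8)
        strands: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        # (prefix array, CpG read positions, CpG state-column indices)
        ot_mask = cpg_pos < Lp
        strands["OT"] = (top[:Lp].copy(), cpg_pos[ot_mask], np.nonzero(ot_mask)[0])
        bot = np.frombuffer(revcomp(frag.top_sequence).encode(), dtype=np.uint8)
        ob_read_pos = m - 2 - cpg_pos  # bottom-strand C of each CpG in read coords
        ob_mask = (ob_read_pos >= 0) & (ob_read_pos < Lp)
        strands["OB"] = (bot[:Lp].copy(), ob_read_pos[ob_mask], np.nonzero(ob_mask)[0])

        for strand_name, (prefix, s_pos, s_col) in strands.items():
            idx = np.nonzero(is_ot if strand_name == "OT" else ~is_ot)[0]
            if idx.size == 0:
                continue
            g = idx.size
            c_all = np.nonzero(prefix == _C)[0]
            template = prefix.copy()
            template[c_all] = _T
            mols = np.tile(template, (g, 1))
            # methylated CpG cytosines stay C
            if s_pos.size:
                meth = states[idx][:, s_col]
                rr, cc = np.nonzero(meth)
                mols[rr, s_pos[cc]] = _C
            # conversion failures: any cytosine that should read T may stay C
            fail_positions: list[tuple[int, ...]] = [()] * g
            if eps > 0 and c_all.size:
                still_t = mols[:, c_all] == _T
                fail = still_t & (rng.random((g, c_all.size)) < eps)
                rr, cc = np.nonzero(fail)
                mols[rr, c_all[cc]] = _C
                for r, c in zip(rr.tolist(), cc.tolist()):
                    fail_positions[r] = fail_positions[r] + (int(c_all[c]),)
            # PCR duplication: geometric copy number, optionally biased.
            # The cytosine tilt is centred at the fragment's expected
            # retained-C count so dup_c_bias controls *differential*
            # amplification between methylation patterns rather than the
            # overall duplication rate.
            tilt = math.exp(-cfg.dup_length_bias * (m - 150) / 250.0)
            q0 = (1.0 - cfg.dup_geometric_p) * tilt
            if cfg.dup_c_bias != 0.0:
                n_c = (mols == _C).sum(axis=1)
                lv = levels[s_col] if s_col.size else np.zeros(0)
                expected_c = float(
                    (lv + (1.0 - lv) * eps).sum() + eps * (c_all.size - lv.size)
                )
                # tilt exponent bounded so extreme patterns cannot explode
                # the copy number (PCR efficiency is at most ~e^1.5 fold off)
                expo = np.clip(-cfg.dup_c_bias * (n_c - expected_c), -1.5, 1.5)
                q = np.clip(q0 * np.exp(expo), 0.0, 0.95)
            else:
                q = np.full(g, min(q0, 0.999))
            # copies ~ 1 + Geom: P(total=t) = (1-q) q^(t-1)
            copies = np.ones(g, dtype=np.int64)
            active = q > 0
            if active.any():
                u = rng.random(g)
                copies[active] += np.floor(
                    np.log1p(-u[active]) / np.log(q[active])
                ).astype(np.int64)
            expanded = np.repeat(mols, copies, axis=0)
            err_positions = _apply_sequencing_errors(expanded, cfg.seq_error_rate, rng)

            quals = [
                max(2, int(round(cfg.base_quality - cfg.quality_decay * p)))
                for p in range(Lp)
            ]
            iv = frag.interval
            row = 0
            for k, mi in enumerate(idx.tolist()):
                state_str = "".join("M" if s else "u" for s in states[mi])
                mol_id = mol_counter + mi
                for copy_i in range(copies[k]):
                    seq = expanded[row].tobytes().decode()
                    truth = ReadTruth(
                        fragment=iv,
                        strand=strand_name,
                        molecule=mol_id,
                        meth_states=state_str,
                        failure_positions=fail_positions[k],
                        error_positions=err_positions[row],
                    )
                    reads_out.append(
                        BisRead(
                            read_id=(
                                f"{iv.contig}_{iv.start}_{iv.end}_"
                                f"{strand_name}_m{mol_id}_c{copy_i}"
                            ),
                            sequence=seq,
                            qualities=list(quals),
                            truth=truth,
                        )
                    )
                    row += 1
        mol_counter += n_mol
    return reads_out


def flank_sites(fragments: Iterable[RrbsFragment]) -> set[CpGSite]:
    """The MspI-boundary CpGs of a fragment set (both ends of each insert)."""
    out: set[CpGSite] = set()
    for f in fragments:
        iv = f.interval
        if f.flanked_both_ends:
            out.add(CpGSite(iv.contig, iv.start))
            out.add(CpGSite(iv.contig, iv.end))
    return out


def simulate_library(
    genome: ReferenceGenome,
    cfg: SimConfig = SimConfig(),
    profile: MethylomeProfile = MethylomeProfile(),
    flank_profile: MethylomeProfile | None = DEFAULT_FLANK_PROFILE,
    size_window: tuple[int, int] = (150, 400),
    adaptor_overhead_bp: int = 65,
    n_reads_target: int | None = None,
) -> SimResult:
    """End-to-end library simulation: digest, size-select, methylate, read.

    ``flank_profile`` redraws the methylation level of MspI-site CpGs
    (pass ``None`` to keep the single i.i.d. profile everywhere).  When
    ``n_reads_target`` is given, the per-fragment depth is set so the
    expected total read count (including PCR duplicates) matches it.
    """
    rng = np.random.default_rng(cfg.seed)
    cuts = find_mspi_sites(genome)
    fragments = size_select(
        digest(genome, cuts), size_window[0], size_window[1], adaptor_overhead_bp
    )
    sites = find_cpg_sites(genome)
    methylome = sample_methylome(sites, profile, rng=rng)
    if flank_profile is not None and fragments:
        fl = sorted(flank_sites(fragments))
        fl = [s for s in fl if s in methylome]
        if fl:
            methylome = methylome.with_levels(
                sample_methylome(fl, flank_profile, rng=rng).levels
            )
    if n_reads_target is not None:
        if not fragments:
            raise ValueError("no fragments survive size selection")
        mean_copies = 1.0 / cfg.dup_geometric_p
        depth = max(n_reads_target / (len(fragments) * mean_copies), 0.01)
        cfg = replace(cfg, depth=depth)
    reads = simulate_reads(fragments, methylome, cfg, rng=rng)
    return SimResult(genome=genome, fragments=fragments, methylome=methylome, reads=reads)


def write_truth_tsv(reads: Iterable[BisRead], path) -> None:
    """Ground-truth table: one row per read, tab-separated."""
    with open(path, "w") as fh:
        fh.write(
            "read_id\tcontig\tstart\tend\tstrand\tmolecule\tmeth_states"
            "\tfailure_positions\terror_positions\n"
        )
        for r in reads:
            t = r.truth
            if t is None:
                continue
            fh.write(
                f"{r.read_id}\t{t.fragment.contig}\t{t.fragment.start}\t{t.fragment.end}"
                f"\t{t.strand}\t{t.molecule}\t{t.meth_states}"
                f"\t{','.join(map(str, t.failure_positions))}"
                f"\t{','.join(map(str, t.error_positions))}\n"
            )


def write_methylome_tsv(methylome: Methylome, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tpos\tlevel\n")
        for site in sorted(methylome):
            fh.write(f"{site.contig}\t{site.pos}\t{methylome[site]:.6f}\n")
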