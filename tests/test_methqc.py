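"""Post-alignment QC: conversion rate, dedup, coverage, dup-representativeness."""

import numpy as np
import pytest
from scipy import stats

from rrbsqc.align import AlignedRead, AlignStatus, MethylationCall
from rrbsqc.genome import CpGSite, CytosineContext, GenomicInterval
from rrbsqc.methqc import (
    CpGSummary,
    conversion_rate,
    coverage_log_histogram,
    coverage_report,
    cpg_summaries,
    cpg_summaries_from_calls,
    deduplicate,
    duplicate_representativeness,
    methylation_histogram,
    select_test_loci,
)
from rrbsqc.reads import BisRead
from rrbsqc.simulate import (
    Methylome,
    SimConfig,
    rrbs_target_genome,
    simulate_library,
)


def call(pos, ctx, meth, rid="r", contig="c"):
    return MethylationCall(CpGSite(contig, pos), ctx, meth, rid)


def stack_read(rid, seq, start=0, strand="+", contig="c", calls=()):
    iv = GenomicInterval(contig, start, start + len(seq), strand)
    a = AlignedRead(
        read=BisRead(rid, seq, [37] * len(seq)),
        status=AlignStatus.UNIQUE,
        placement=iv,
        source_strand="OT" if strand == "+" else "OB",
        mismatches=0,
    )
    a.calls = list(calls)
    return a


class TestConversionRate:
    def test_99_of_100(self):
        calls = [call(i, CytosineContext.CHH, False) for i in range(99)]
        calls.append(call(99, CytosineContext.CHH, True))
        assert conversion_rate(calls) == 99.0

    def test_all_converted(self):
        calls = [call(i, CytosineContext.CHG, False) for i in range(10)]
        assert conversion_rate(calls) == 100.0

    def test_cpg_calls_excluded(self):
        calls = [call(0, CytosineContext.CPG, True)] * 5 + [
            call(1, CytosineContext.CHH, False)
        ]
        assert conversion_rate(calls) == 100.0

    def test_no_noncpg_calls_warns_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(conversion_rate([call(0, CytosineContext.CPG, True)]))


class TestDeduplicate:
    def test_23_reads_collapse_to_9(self):
        """A 23-read stack with 9 distinct molecules (coordinates+sequence)."""
        variants = [f"{p}GG" + "ACGT" * 5 for p in "CT"]  # 2 start states
        seqs = [v + suffix for v in variants for suffix in ("AAAA", "AATA", "ATTA")]
        seqs += [variants[0] + "TTTA", variants[1] + "TTTT", variants[0] + "GTTA"]
        assert len(seqs) == 9
        mult = [4, 3, 3, 3, 2, 2, 2, 2, 2]  # sums to 23
        reads = []
        i = 0
        for s, k in zip(seqs, mult):
            for _ in range(k):
                reads.append(stack_read(f"r{i}", s))
                i += 1
        assert len(reads) == 23
        uniq, multiplicities = deduplicate(reads)
        assert len(uniq) == 9
        assert sum(multiplicities.values()) == 23

    def test_all_distinct_is_identity(self):
        reads = [stack_read(f"r{i}", "ACGT" * 6, start=i * 30) for i in range(5)]
        uniq, mult = deduplicate(reads)
        assert len(uniq) == 5 and all(v == 1 for v in mult.values())

    def test_same_position_different_methylation_kept(self):
        a = stack_read("a", "CGGAACGA")
        b = stack_read("b", "CGGAATGA")  # same locus, different CpG state
        uniq, _ = deduplicate([a, b])
        assert len(uniq) == 2

    def test_rejects_non_unique_status(self):
        bad = AlignedRead(read=BisRead("x", "ACGT", [37] * 4), status=AlignStatus.AMBIGUOUS)
        with pytest.raises(ValueError):
            deduplicate([bad])


class TestCpgSummaries:
    def test_tally(self):
        calls = [call(10, CytosineContext.CPG, True, rid=f"r{i}") for i in range(3)]
        calls.append(call(10, CytosineContext.CPG, False, rid="r3"))
        (s,) = cpg_summaries_from_calls(calls)
        assert (s.n_methylated, s.n_total, s.frequency) == (3, 4, 0.75)

    def test_absent_sites_absent_and_noncpg_ignored(self):
        calls = [call(5, CytosineContext.CHH, False)]
        assert cpg_summaries_from_calls(calls) == []

    def test_truth_recovery_on_simulation(self, aligned, sim):
        """Called per-CpG frequencies track the methylome within 3 binomial SE.

        PCR copies are correlated observations of the same molecule, so the
        binomial error model applies at the molecule level: restrict to the
        first sequenced copy of each molecule.
        """
        first_copies = [a for a in aligned if a.read.read_id.endswith("_c0")]
        summaries = cpg_summaries(first_copies, "all_reads")
        outliers = 0
        checked = 0
        for s in summaries:
            if s.n_total < 10:
                continue
            level = sim.methylome.get(s.site)
            se = np.sqrt(max(level * (1 - level), 1e-4) / s.n_total)
            checked += 1
            # conversion failure inflates apparent methylation by <=(1-m)*eps
            if abs(s.frequency - level) > 3 * se + 0.011:
                outliers += 1
        assert checked > 300
        # ~0.3% of sites exceed 3 SE by chance; allow 2%
        assert outliers / checked < 0.02


class TestCoverageReport:
    def test_example(self):
        summaries = [
            CpGSummary(CpGSite("c", i), 0, n) for i, n in enumerate([1, 5, 10])
        ]
        r = coverage_report(summaries)
        assert (r.n_cpgs_1x, r.n_cpgs_5x, r.n_cpgs_10x) == (3, 2, 1)
        assert r.mean_coverage == pytest.approx(16 / 3)

    def test_all_singletons(self):
        summaries = [CpGSummary(CpGSite("c", i), 0, 1) for i in range(4)]
        assert coverage_report(summaries).mean_coverage == 1.0

    def test_empty_warns_zeroes(self):
        with pytest.warns(UserWarning):
            r = coverage_report([])
        assert r.n_cpgs_1x == 0

    def test_duplicates_never_reduce_coverage(self, aligned):
        with_dup = coverage_report(cpg_summaries(aligned, "all_reads"))
        without = coverage_report(cpg_summaries(aligned, "unique_only"))
        assert with_dup.mean_coverage >= without.mean_coverage
        assert with_dup.n_cpgs_1x == without.n_cpgs_1x  # dedup keeps >=1 read/key
        r = with_dup
        assert r.n_cpgs_10x <= r.n_cpgs_5x <= r.n_cpgs_1x


class TestHistograms:
    def test_bin_edges(self):
        summaries = [
            CpGSummary(CpGSite("c", 0), 0, 10),  # 0%
            CpGSummary(CpGSite("c", 1), 999, 1000),  # 99.9%
            CpGSummary(CpGSite("c", 2), 1, 20),  # exactly 5%
            CpGSummary(CpGSite("c", 3), 10, 10),  # 100% -> closed last bin
        ]
        h = methylation_histogram(summaries)
        assert h[0] == 1 and h[19] == 2 and h[1] == 1
        assert h.sum() == 4

    def test_bimodal_profile_recovered(self, aligned, sim):
        """The <5% histogram mass reflects the simulated low fraction."""
        summaries = [s for s in cpg_summaries(aligned, "all_reads") if s.n_total >= 10]
        h = methylation_histogram(summaries)
        frac_low_bin = h[0] / h.sum()
        # interior CpGs: 0.60 low, MspI-flank CpGs mostly low; conversion
        # failure and small-sample noise smear some mass out of the first bin
        assert 0.45 < frac_low_bin < 0.85

    def test_coverage_log_histogram(self):
        summaries = [
            CpGSummary(CpGSite("c", 0), 0, 10),
            CpGSummary(CpGSite("c", 1), 0, 1),
            CpGSummary(CpGSite("c", 2), 0, 100),
        ]
        edges, counts = coverage_log_histogram(summaries)
        assert counts.sum() == 3
        assert counts[0] == 1  # log10(1)=0
        assert counts[np.searchsorted(edges, 1.0)] == 1  # log10(10)=1
        assert counts[np.searchsorted(edges, 2.0)] == 1


def engineered_locus(n_unique=12, n_dup_extra=11, n_cpgs=5, seed=0):
    """A read stack over one locus with intermediate per-CpG methylation."""
    rng = np.random.default_rng(seed)
    reads = []
    patterns = set()
    i = 0
    while len(reads) < n_unique:
        states = rng.random(n_cpgs) < 0.5
        seq = "".join("C" if s else "T" for s in states) + "A" * 20
        if seq in patterns:
            continue
        patterns.add(seq)
        calls = [
            call(2 * j, CytosineContext.CPG, bool(states[j]), rid=f"u{i}")
            for j in range(n_cpgs)
        ]
        reads.append(stack_read(f"u{i}", seq, calls=calls))
        i += 1
    base = reads[:]
    for k in range(n_dup_extra):  # balanced (unbiased) PCR duplication
        src = base[k % len(base)]
        dup = stack_read(
            f"d{k}",
            src.read.sequence,
            calls=[
                MethylationCall(c.site, c.context, c.methylated, f"d{k}")
                for c in src.calls
            ],
        )
        reads.append(dup)
    return reads


class TestSelectTestLoci:
    def test_engineered_locus_selected(self):
        reads = engineered_locus()
        loci = select_test_loci(reads, min_unique_reads=11, min_diff_cpgs=4)
        assert len(loci) == 1 and len(loci[0]) == len(reads)

    def test_saturated_methylation_rejected(self):
        reads = []
        for i in range(12):
            seq = "CCCCC" + "A" * 20  # all CpGs fully methylated
            calls = [call(2 * j, CytosineContext.CPG, True, rid=f"r{i}") for j in range(5)]
            reads.append(stack_read(f"r{i}", seq + "ACGT"[i % 4] + str(i), calls=calls))
        assert select_test_loci(reads, min_unique_reads=5) == []

    def test_too_few_unique_reads_rejected(self):
        reads = engineered_locus(n_unique=8, n_dup_extra=20)
        assert select_test_loci(reads, min_unique_reads=11) == []


class TestDuplicateRepresentativeness:
    def test_worked_example_vectors(self):
        res = duplicate_representativeness(
            unique_frequencies=[0.44, 0.67, 0.11, 0.22],
            all_frequencies=[0.61, 0.74, 0.043, 0.22],
            n_unique_reads=9,
            n_all_reads=23,
        )
        assert round(res.r_squared, 2) == 0.95
        assert round(res.p_value, 2) == 0.03

    def test_p_value_equals_t_transformation(self):
        """scipy's Pearson p matches the explicit t = r*sqrt(n-2)/sqrt(1-r^2)."""
        u = [0.44, 0.67, 0.11, 0.22]
        a = [0.61, 0.74, 0.043, 0.22]
        res = duplicate_representativeness(unique_frequencies=u, all_frequencies=a)
        r = np.sqrt(res.r_squared)
        t = r * np.sqrt(2) / np.sqrt(1 - r**2)
        p_manual = 2 * stats.t.sf(t, df=2)
        assert res.p_value == pytest.approx(p_manual, rel=1e-9)

    def test_identical_vectors_r2_one(self):
        v = [0.1, 0.5, 0.9, 0.3]
        res = duplicate_representativeness(unique_frequencies=v, all_frequencies=v)
        assert res.r_squared == pytest.approx(1.0)

    def test_zero_variance_degenerate(self):
        with pytest.warns(UserWarning):
            res = duplicate_representativeness(
                unique_frequencies=[0.5, 0.5, 0.5],
                all_frequencies=[0.1, 0.2, 0.3],
            )
        assert res.degenerate and np.isnan(res.r_squared)

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            duplicate_representativeness(
                unique_frequencies=[0.1, 0.2], all_frequencies=[0.1, 0.2]
            )

    def test_from_read_stack(self):
        reads = engineered_locus()
        res = duplicate_representativeness(reads)
        assert res.n_all_reads == len(reads)
        assert res.n_unique_reads == 12
        assert res.r_squared > 0.9  # unbiased duplication: pools nearly identical

    def test_pcr_bias_degrades_r2(self):
        """Strong cytosine-count amplification bias lowers locus r² vs no bias."""
        genome = rrbs_target_genome(60_000, seed=21)
        medians = {}
        for bias in (0.0, 0.6):
            sim = simulate_library(
                genome,
                SimConfig(seed=13, depth=30.0, dup_geometric_p=0.35, dup_c_bias=bias),
                profile=__import__("rrbsqc").MethylomeProfile(
                    frac_low=0.05, frac_high=0.05, mid_bump_weight=0.0
                ),
                flank_profile=None,
            )
            from rrbsqc import align_reads, build_index

            idx = build_index(genome)
            aligned = [
                a
                for a in align_reads(sim.reads, idx, genome)
                if a.status is AlignStatus.UNIQUE
            ]
            loci = select_test_loci(aligned, min_unique_reads=11, min_diff_cpgs=4)
            r2 = [
                duplicate_representativeness(stack).r_squared
                for stack in loci
                if not duplicate_representativeness(stack).degenerate
            ]
            assert len(r2) >= 20
            medians[bias] = float(np.median(r2))
        assert medians[0.0] > medians[0.6]
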