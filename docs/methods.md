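# Methods

This note describes the models behind `rrbsqc`: what the simulator
generates, what the QC statistics measure, which numerical choices were
made where the design was genuinely open, and what passing the test suite
does and does not demonstrate about real libraries.

## The molecular model

A directional RRBS library is modelled in five stages.

**Digestion.** MspI recognises `CCGG` and cleaves 5' of the internal CpG,
so every cut position is the first base of a `CGG`. In-silico digestion
reports one cut per forward-strand `CCGG` occurrence (the site is
palindromic; overlapping occurrences such as `CCGGCCGG` each count). An
internal fragment spans consecutive cuts `[p_i, p_j)`; end repair fills in
the 5'-CG overhangs, duplicating each boundary CpG into both neighbouring
fragments, so the physical top strand is `genome[p_i : p_j] + "CG"` and
always reads `CGG ... CCG`. Chromosome-terminal pieces lack an MspI end
(and hence the adaptor structure) and are excluded from simulated
libraries by default. Optional digestion blocking at sites whose outer C
is methylated is not modelled in v1: the outer C of `CCGG` sits in CHG
context, which is essentially unmethylated in mammalian somatic tissue,
and the pipeline's reference figures assume complete digestion.

**Size selection.** The gel window is interpreted as the size of the
*ligated* molecule: a fragment is kept when
`insert + adaptor_overhead_bp` falls in `[min_bp, max_bp]`, defaults
150–400 bp with a 65 bp overhead (the two-step adaptor dimer length).
Whether published windows include adaptors is ambiguous in practice, so
both the window and the overhead are parameters; setting the overhead to 0
size-selects on the bare insert.

**Methylome.** Per-CpG methylation levels are drawn independently from a
mixture emulating an adult-brain methylome: with probability `frac_low`
(0.60) uniform on [0, 0.05), with `frac_high` (0.275) uniform on
(0.95, 1], with `mid_bump_weight` (0.02) uniform on [0.45, 0.50) — the
small reproducible excess seen in brain data — and the remainder uniform
between the modes. The mixture mean is ≈0.345. Within-mode shapes are a
modelling choice (published data constrain the mode masses, not the
within-mode distribution); uniform was chosen for transparency.

CpGs at the MspI cut sites themselves (`flank_profile`) default to a
strongly hypomethylated mixture (`frac_low = 0.95`). `CCGG` sites
concentrate in hypomethylated CpG islands — this is the classical
HpaII-site definition of islands — and raw-read base composition from real
RRBS lanes shows no large cytosine spike at read position 1, which there
would be if start-site CpGs followed the genome-wide bimodal mixture
(every read's first base is C exactly when its start CpG is methylated).
The head/tail C-ratio check below is only a meaningful conversion metric
under this flank behaviour. Pass `flank_profile=None` to use one i.i.d.
profile everywhere.

**Conversion and reading.** Each fragment receives
`Poisson(depth)` molecules (default depth 20). Per molecule, each CpG is
methylated by a Bernoulli draw of its level (shared by both strands of the
molecule), and the sequenced strand is original-top with probability
`ot_fraction` (default 0.5). On the sequenced strand every cytosine that
is not a methylated CpG deaminates to T, except that each such cytosine
independently survives as C with probability `conversion_failure`
(default ε = 0.01, matching ~99% conversion chemistry). Conversion failure
is modelled per-cytosine i.i.d.; aggregate rates cannot distinguish this
from per-molecule failure, so a whole-molecule mode is deliberately not
implemented in v1. The read is the first `read_length` (50) bases of the
converted strand — for OB molecules the reverse complement, which also
starts at an MspI end, so both strands begin `CGG`/`TGG`. Fragments
shorter than the read length yield truncated reads, never padded ones.
Hydroxymethylation is indistinguishable from methylation after bisulfite
treatment and is not modelled.

**PCR and sequencing.** Conversion precedes amplification, so PCR copies
share their molecule's conversion outcome while sequencing errors are
independent per copy (substitution-only, probability `seq_error_rate` =
2×10⁻⁴ per base, consistent with phred ≈ 37; qualities default to a
constant 37 with an optional linear decay). Copy numbers follow a
geometric law: a molecule yields `t` reads with probability
`(1-q) q^(t-1)`, where `q = (1 - dup_geometric_p) · tilt`
(default `dup_geometric_p` 0.5 → mean 2 copies). The bias tilt is
`exp(-a·(len-150)/250 - b·(nC - E[nC]))` with `a = dup_length_bias`,
`b = dup_c_bias`, `nC` the molecule's retained cytosine count and `E[nC]`
its expectation under the fragment's methylome. Centring at `E[nC]` makes
`b` control *differential* amplification between methylation patterns at a
comparable overall duplication rate; an uncentred tilt would simply switch
duplication off for every molecule once `b·nC` is large, which removes the
failure mode the parameter exists to create. The exponent is clipped to
±1.5 and `q` to 0.95 so extreme patterns cannot produce unbounded copy
numbers. Defaults are a = b = 0 (unbiased amplification).

All randomness flows from a single seed: identical configurations produce
byte-identical FASTQ.

## Synthetic genomes

`random_genome` draws i.i.d. bases (uniform by default).
`rrbs_target_genome` uses A,C,G,T = 0.20, 0.30, 0.30, 0.20 and is the
default substrate for library-level simulations: RRBS covers only the
CCGG-flanked ~2–3% of a mammalian genome, heavily weighted toward CpG
islands at ~60% GC, and the GC-rich composition reproduces realistic MspI
site and interior-CpG densities. It also matters statistically at desk
scale: a uniform 100 kb genome yields only ~180 size-selected fragments,
so composition statistics (notably the head/tail C ratio) inherit large
genome-realisation noise (SD ≈ 0.14 across genome seeds), whereas the
GC-rich genome yields ~340 fragments and SD ≈ 0.08 around the same
expected value. Neither composition models CpG depletion, repeats,
isochores or N gaps; conclusions from simulations are about the pipeline's
statistical machinery, not about any real genome's sequence organisation.

## QC statistics

**GG start fraction.** Every correctly digested directional RRBS read has
G at positions 2–3; the simulator reproduces this exactly when sequencing
error is off, and at ≈99.96% at the default error rate. The alarm
threshold is 0.95 (below it, suspect incomplete digestion or library
contamination).

**Head/tail C ratio.** Total C count at read positions 1–10 divided by
that at the last ten positions. Residual cytosines in a well-converted
library (methylated CpGs plus conversion failures) are spread roughly
evenly once the flank CpG is hypomethylated, so the ratio sits near 1;
incomplete conversion or position-dependent miscalls push it away. The
published windows are "1–10" versus "40–50", which are unequal widths
(10 vs 11); the default here is the equal-width 1–10 vs 41–50 and both
windows are explicit parameters, so either reading is available.

**Trimming.** Adaptor clipping is exact-match (first occurrence wins,
with a proper adaptor prefix recognised at the read end for read-through);
reads shorter than 20 bp after trimming are dropped, as are reads with
mean phred below 20 (the low-quality threshold is not pinned by published
pipelines; 20 is common practice and configurable).

**Conversion rate.** 100 × converted / total over CHH+CHG calls only
(H = any base but G). Mammalian non-CpG methylation is negligible, so
residual non-CpG cytosines estimate bisulfite failure; CpG calls are
excluded because genuine methylation would deflate the estimate. On the
designated mitochondrial contig a second, deliberately different estimator
uses *all* contexts including CpG, because the mammalian MT genome is
unmethylated; apparent MT CpG methylation above 2% is flagged.

## Alignment

Directional three-letter alignment: read and both reference strands are
collapsed C→T; candidates come from exact 16-mer seeds (three or more
windows per 50-mer: with a ≤2 mismatch budget the pigeonhole principle
guarantees one clean window, making the seeded search exactly equivalent
to scoring every offset on both strands — the test suite verifies this
equivalence against a brute-force scorer read-for-read). Reads too short
for three disjoint windows fall back to an exhaustive vectorised scan,
preserving exactness. Placement is best-unique: one minimal-mismatch
placement within the budget (default 2) is `unique`; ties — including ties
across strands — are `ambiguous` and discarded rather than broken
arbitrarily; no indels are modelled (MspI 50-mers align end-to-end), so
CIGARs are always `<len>M` and MAPQ is fixed at 255 (unavailable). SAM
output is 1-based, FLAG 16 with reference-orientation SEQ for OB reads,
`NM` carrying the reduced-space mismatch count, `XM` the per-base call
string (Z/z CpG, X/x CHG, H/h CHH) and `XG` the strand of origin.

Methylation calls: for every genomic cytosine on the read's source strand,
read C = methylated, read T = converted, any other base (sequencing error)
= no call. Reverse-strand CpG calls are re-attributed to the forward C of
the dinucleotide so both strands tally onto one site. Cytosines within two
bases of a contig end, and contexts containing N, are skipped rather than
guessed.

## Duplicates and the representativeness test

In RRBS most reads at a locus share their MspI-defined 5' end, so
coordinate-only deduplication would discard genuinely independent
molecules. The duplicate key is (contig, 5' position, strand, read
sequence): same-coordinate reads with different methylation patterns or
sequencing errors stay in the unique pool.

Whether the *full* pool (duplicates included) may be used for coverage is
decided by the representativeness test: at each locus with ≥11
deduplicated reads and ≥4 CpGs methylated strictly between 0 and 1 in the
unique pool, the per-CpG methylation frequencies of the unique pool and
the full pool are correlated (Pearson). r² near 1 means amplification was
balanced and duplicates are a fair proxy for molecule counts; a weak
correlation indicates pattern-selective PCR. The two-sided p-value comes
from `t = r·sqrt(n-2)/sqrt(1-r²)` on n−2 degrees of freedom (with n = 4
CpGs and r² = 0.95 this reproduces the published p = 0.03); fewer than 3
paired sites is an error, zero variance in either vector a flagged
degenerate result. The published selection rule says "more than four"
differentially methylated sites while its own worked example has exactly
four; defaults here are ≥11 reads and ≥4 sites, both parameters.

Coverage reports count CpGs at ≥1X/5X/10X and average coverage over
*covered* CpGs only (the convention consistent with published mean
coverages well below 2 at low depth); histograms use 5-percentage-point
methylation bins with the last bin closed at 100%, and log10 coverage bins
of width 0.1.

## Control regions and pooling

Region methylation is coverage-weighted (Σ methylated / Σ total within the
interval) rather than the mean of per-CpG frequencies — published
practice does not pin this down; the unweighted alternative is available
(`region_percent(..., weighted=False)`). A region passes when it lies
within `k_sd` (default 3) × max(reference SD, 1 pp) of its reference mean;
unmethylated housekeeping controls must additionally stay below 5%. The
bundled reference table carries per-subject adult-brain percentages with
their across-subject means ± SDs for six imprinted and two unmethylated
CpG islands (hg19); imprinting is tissue-specific, so other tissues need
their own table (the bundled sperm column is annotation only and is never
used in checks).

Lane design math is exact: with an equimolar pool of `n` bisulfite
libraries and a non-bisulfite spike-in fraction `s`, each library occupies
`100·(1-s)/n` percent of the lane. Per-position Shannon entropy over the
first bases quantifies the diversity problem the spike-in addresses
(0 bits at the monomorphic GG, 2 bits at a balanced position).

## Problem sizes and numerical notes

Simulations in the test suite run at desk scale chosen for statistical
sufficiency: 20 kb genomes for unit fixtures; 50–100 kb genomes and
10⁴–10⁵ reads where a bound is checked against binomial sampling error
(e.g. conversion-rate recovery uses ≥10⁵ non-CpG calls so the ±0.2 pp
tolerance sits at >6 standard errors); aligner–oracle equivalence uses 20
genomes of 10–50 kb with 1 000 reads each, checked read-for-read. Per-CpG
frequency recovery is asserted at the molecule level (first PCR copy per
molecule) because duplicate reads are correlated observations and the
binomial error model applies to molecules, not reads.

Tie-breaks and degenerate inputs: equal-score alignment hits are never
broken by order — they yield `ambiguous`; empty call sets produce NaN with
a warning rather than exceptions wherever a report can still be assembled;
N bases never form MspI sites, CpG sites or classifiable contexts.

## Known limitations

Single-end, substitution-only, fixed read length; no adapter read-through
chemistry beyond exact-match trimming; no non-directional (CTOT/CTOB)
strands; no per-molecule conversion failure mode; synthetic genomes have
no repeat structure, so ambiguous alignments are rarer than in mammalian
data; the methylome model is spatially uncorrelated apart from the
MspI-flank override, so domain-scale methylation structure (islands,
shores, partially methylated domains) is not represented. Passing tests
demonstrate internal correctness and parameter recovery under these
conditions, not performance on real libraries.
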