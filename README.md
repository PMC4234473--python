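# rrbsqc

Quality control and simulation toolkit for **directional reduced-representation
bisulfite sequencing (RRBS)**.

RRBS measures DNA methylation at single-CpG resolution by digesting genomic
DNA with MspI (`C^CGG`), size-selecting the fragments, bisulfite-converting
them (unmethylated C → U, read as T; 5-methylcytosine protected) and
sequencing 50-base single-end reads from either the original top (OT) or
original bottom (OB) strand. This protocol stamps strong structure onto the
data — every read starts `CGG` or `TGG`, cytosines are scarce, most reads at
a locus share their MspI-defined 5' end — and that structure is exactly what
makes careful QC both possible and necessary. `rrbsqc` implements the
operational QC layer for such experiments, for people running or reviewing
RRBS libraries and for people developing methylation callers who need
ground-truth data:

* **In-silico digestion** — MspI cut maps, end-repaired fragments
  (`CGG ... CCG`), gel-window size selection.
* **Read simulator** — a generative model of the full library protocol
  (bimodal brain-like methylome, per-cytosine conversion failure ε,
  strand-balanced directional reads, geometric PCR duplication with optional
  length/cytosine amplification bias, sequencing error), emitting FASTQ plus
  complete per-read ground truth.
* **Pre-alignment QC** — per-position base composition, the head/tail
  cytosine ratio (≈1 in a well-converted library), the GG-at-positions-2/3
  digestion check (alarm below 95%), adaptor trimming and length/quality
  filters with exact counters.
* **Alignment** — a minimal directional three-letter aligner: candidates
  from 16-mer seeds in C→T-reduced space, best-unique placement with ≤2
  mismatches, ties discarded; per-cytosine methylation calls (CpG/CHG/CHH)
  and SAM export with `XM`/`XG` tags that genome browsers and `samtools`
  accept. The seeded search is provably (and, in the test suite, empirically
  read-for-read) equivalent to brute-force scoring of every offset.
* **Post-alignment QC** — conversion rate from non-CpG (CHH+CHG) calls,
  per-CpG methylation summaries, 5%-bin methylation and log10-coverage
  histograms, 1X/5X/10X coverage with and without duplicates, and the
  **duplicate-representativeness test**: at loci with ≥11 unique reads and
  ≥4 differentially methylated CpGs, Pearson-correlate per-CpG methylation
  between the deduplicated and full read pools; r² near 1 licenses using
  duplicates in coverage statistics, low r² flags PCR amplification bias
  (p from `t = r·√(n−2)/√(1−r²)`).
* **Controls & pooling** — imprinted-region positive controls with a bundled
  adult-brain reference table, the unmethylated-mitochondrial-genome negative
  control, equimolar lane-fraction math for non-bisulfite spike-ins, and
  first-base Shannon-entropy diagnostics, plus utilities for the two-step
  methylated-adaptor oligo set (lengths, 65 bp adaptor-dimer, 6-nt index
  extraction).

See `docs/methods.md` for the underlying models, parameter defaults and
their rationale, and known limitations.

## Worked example

Simulate and QC a small library end to end (a 50 kb GC-rich synthetic
genome; all numbers below are the actual program output):

```bash
python - <<'EOF'
from rrbsqc.io import write_fasta
from rrbsqc.simulate import rrbs_target_genome
write_fasta(rrbs_target_genome(50_000, seed=11), "ref.fa")
EOF
rrbsqc digest   --fasta ref.fa --out fragments.bed
rrbsqc simulate --fasta ref.fa --n-reads 20000 --seed 7 --out-prefix sim
rrbsqc fastq-qc sim.fastq --report qc.json
rrbsqc align    --fasta ref.fa --fastq sim.fastq --sam aln.sam
rrbsqc meth-qc  aln.sam --report meth.json --cpg-out cpg.tsv
rrbsqc pool-design --libraries 4 --spike 0.30
```

```
405 fragments, 173 within 150-400 bp; wrote fragments.bed
173 fragments, 20310 reads -> sim.fastq (+ .truth.tsv, .methylome.tsv)
kept 20310/20310 reads; C ratio 1.066; GG start fraction 0.9999; report -> qc.json
20310 reads: 20310 unique, 0 ambiguous, 0 unaligned -> aln.sam
report -> meth.json (28 dup-test loci)
4 bis libraries + 30.0% spike-in -> 17.5% of the lane per library
```

Reading the output: 173 fragments survive the 150–400 bp gel window (insert
plus the 65 bp adaptor overhead). The **C ratio** of 1.066 says residual
cytosines are evenly spread between the first and last ten read positions —
the signature of complete bisulfite conversion — and the **GG start
fraction** of 0.9999 confirms the MspI read structure (values below 0.95
would trigger a digestion alarm). All reads place uniquely because the
synthetic genome has no repeats. Inside `meth.json`, the conversion rate
recovered from CHH+CHG calls is 99.01% (the library was simulated with
ε = 0.01, i.e. a true conversion rate of 99%), unique-read coverage averages
8.0X versus 62.0X with duplicates over the same 1 546 covered CpGs, and the
28 loci eligible for the duplicate-representativeness test show r² values
such as 0.966 (p = 1.2×10⁻⁵) and 0.992 — amplification was unbiased, so
duplicates may be used for coverage here.

The library API mirrors the CLI one-to-one (`rrbsqc.simulate_library`,
`rrbsqc.align_reads`, `rrbsqc.cpg_summaries`,
`rrbsqc.duplicate_representativeness`, ...), and simulated reads carry their
ground truth (source interval, strand of origin, per-CpG states, error
positions) for validating callers.

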