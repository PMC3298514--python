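# Methods

This note documents the models, algorithms and numerical choices behind
`snpmine`, the assumptions they rest on, and what the synthetic-data tests do
and do not demonstrate.

## Read cleaning

Trimming runs in a fixed order: barcode, adapters, quality, fixed terminal
bases, then the gates.  The order matters because the length gates are meant
to apply to the *final* read, and because quality trimming should not see
barcode/adapter bases.

* **Barcodes** are matched exactly (0 mismatches) against the first 6 bases.
  Exact matching is conservative: a 1-mismatch tolerance would admit reads
  whose true origin is ambiguous between two barcodes at Hamming distance 2.
* **Quality trimming** implements the modified-Mott algorithm: each base
  scores `limit − p` (error probability `p`, limit 0.05) and the kept region
  is the contiguous segment with the maximal running sum (Kadane's
  algorithm).  This is the de facto meaning of a single "quality limit"
  parameter in common trimming tools.  Reads without quality data skip this
  stage.
* **Adapters** are located by infix (semi-global) alignment of the adapter
  and its reverse complement inside the read; a hit needs ≥10 matched bases
  at ≥90% identity.  A hit whose midpoint lies in the 5' half truncates the
  read start, otherwise the read end.
* **Terminal trimming** removes 1 base at the 5' end and 15 at the 3' end by
  default, where 454 base quality is systematically poor.
* **Gates**: reads with more than 2 ambiguous bases, shorter than 100 bp or
  longer than 800 bp after all trimming are rejected with a typed reason;
  every input read ends up in exactly one of {kept} ∪ {rejected(reason)}.

## Clonal-read removal

Because the libraries are random-primed rather than sheared, true PCR
duplicates start at the same template base: they share their initial
sequence exactly.  Clustering is greedy, CD-HIT style: reads sorted by
length descending (ties by id, which makes the result invariant to input
order), bucketed by their first 6 bases; a read joins the first cluster
whose representative matches it at ≥98% identity, where identity is computed
by prefix-anchored semi-global alignment (edlib) of the shorter read against
the representative and normalized by the shorter length.  The longest member
(the representative) is kept.  Greedy single-linkage to the representative —
not transitive closure — is the documented contract; the cluster identity
bound therefore holds against the representative, not between arbitrary
members.

## SNP detection and haplotypes

All calling happens on the padded multiple alignment imported from ACE or
SAM (positions reported to the user are 1-based on the ungapped consensus).

* **Potential SNP**: a pad-free column with ≥2 distinct bases each supported
  by ≥2 reads (support counted across genotypes by default; a per-genotype
  mode is available).  Columns containing pads are recorded as indel columns
  — excluded from candidacy but counted against flank cleanliness.
* **Haplotype reconstruction** groups reads by their allele vectors over the
  potential-SNP columns.  Reads are processed left to right (by first
  covered column, widest first); a read joins the compatible haplotype with
  which it shares the most defined columns, founding a new haplotype only
  when it conflicts with every existing one.  A final parsimony pass merges
  any fragment that is still compatible with another haplotype into its best
  partner, so the reported count is the minimum number of haplotypes
  consistent with the reads.  Preferring most-shared over largest, and
  merging leftover fragments, are deliberate: with ~280-bp reads a
  coincidental short agreement between two alleles, or a long monomorphic
  stretch, would otherwise split chains and inflate the count — and the
  count is exactly what the chimera test consumes.  Single-read haplotypes
  are retained but flagged low-support.
* **Quality D-value**: with `m` potential-SNP columns, each haplotype's
  divergence `n_i` is the number of columns where its allele differs from
  the column's read-majority allele (ties broken toward the largest
  haplotype); `D` is the population standard deviation of `n_i/m`.  `D = 0`
  whenever `m = 0` or there is a single haplotype.  `D` is invariant under
  haplotype relabeling.  High `D` indicates a contig mixing paralogs with
  alleles.  The normalization is this package's concrete reading of the
  verbal definition; published per-contig values from other tools are not
  bit-comparable.
* **Intra/inter classification**: *intra* requires both alleles ≥2-supported
  inside one genotype (heterozygosity); *inter* requires at least one
  genotype carrying only allele 1 and another only allele 2.  A column
  showing both reports *inter* with a both-flag, as the between-genotype
  segregation is the more informative property for mapping.
* **Reliability filter**, in check order: `short_flank` (50 bp to either
  contig end), `dirty_flank` (another potential SNP or indel column within
  50 bp), `homopolymer` (inside or immediately adjacent to a run of ≥3
  identical consensus bases — 454's dominant error context starts at
  length-3 runs), `low_support`, `low_quality` (mean column Phred < 20,
  skipped without qualities).  Thresholds are parameters with these
  defaults.
* **Chimera ceiling**: a clean single-locus contig of `g` genotypes at
  ploidy `p` can show at most `g·p` haplotypes (8 for four diploids).
  Contigs with more are flagged and yield no markers unless explicitly kept.
  The flag uses strict inequality (`h > ceiling`).

## Marker uniqueness

The 101-bp flank (variant at base 51) is searched against every contig of
the same assembly:

* exact 11-mer seeds over both strands; seeds clustered by diagonal;
* gapped Smith–Waterman extension (match +1, mismatch −2, gap open −5, gap
  extend −2; affine DP JIT-compiled with numba) in a ±25-column band around
  the seeded window;
* bit score `S′ = (λS − ln K)/ln 2` with ungapped DNA constants λ = 1.28,
  K = 0.46, and `E = m·n·2^(−S′)` with `m` the query length and `n` the
  total contig length of the database, the source contig included.

The contract is *threshold equivalence*, not bit-exact reproduction of any
particular search engine: on the fixtures, retain/discard decisions at
E ≤ 1e-20 are identical to an exhaustive local-alignment scan of every
contig with the same scoring (verified against Biopython's PairwiseAligner
as an independent oracle).  A word size of 11 guarantees a seed for any
≥95%-identity, ≥50-bp match, far below the E-20 detectability bound.  A
marker is retained only if it has exactly one above-threshold hit and that
hit lies on its source contig; tandem duplications inside the source contig
produce two distinct hit intervals and therefore count as multi-hit.

## Assembly comparison

Summary statistics (contig count, mean/total length, reads per contig,
length histogram over <200 / 200–999 / 1000–1999 / ≥2000 bp, N50 as an
extra field, contigs containing all genotypes) are exact arithmetic.
Transcriptome coverage divides assembled bases by a reference gene
complement (default: 41,000 genes × 2,000 bp, the rice transcriptome).
Redundancy reports reuse the search engine per contig of assembly A against
an index of assembly B, histogram the above-threshold hit counts (0, 1,
2–5, 6–10, >10) and report the exactly-one-hit fraction; self-comparison
excludes each contig's trivial identity hit.  For references matched by ≥2
contigs, hits overlapping by ≥20 bp classify the reference as redundantly
covered, otherwise as tiled ("adjacent"); the 20-bp threshold is a package
choice.

## Synthetic data

The generator emulates the statistical structure of a four-genotype,
barcoded 454 EST experiment on a highly heterozygous outbreeder:

* **Polymorphism model.**  Polymorphic sites are *shared* across the
  breeding pool: sites are placed per-bp at the between-genotype density
  (default 1/30).  At each site a genotype is heterozygous with probability
  `intra_rate / inter_rate` (0.6 at the defaults, making the within-genotype
  heterozygous density 1/50) and otherwise fixed for one of the two alleles
  at random.  Treating the two printed densities as nested rather than
  additive is the only reading under which both hold simultaneously;
  additive independent placement would give one variant per ~9 bp and no
  clean 101-bp windows at all.
* **Reads** are random-primed fragments: uniform starts (sampled without
  replacement within a gene, so independent reads never coincide exactly and
  clonality stays identifiable), truncated-normal lengths (mean 283 bp, the
  post-trim mean of the emulated platform), a genotype barcode, flat Phred-40
  qualities.  Homopolymer errors insert or delete one base at runs ≥3 with a
  configurable per-run rate (default 0 — error-free is the reference
  condition for recovery tests).  Clonal duplicates are added as possibly
  truncated copies of existing reads until they form `clonal_rate` (default
  0.35) of the output.
* **Assembly stand-in** (`emit_true_assembly`) replaces the external
  assembler so downstream stages are testable: `truth` mode builds one
  contig per gene with all alleles co-assembled; `split` mode separates the
  allele copies of a fraction of genes into two contigs (the
  over-discriminating OLC failure); `merged` mode co-assembles paralog pairs
  into chimeric contigs (the k-mer-graph failure).  Reads are placed by
  edlib alignment to their true source allele and the consensus is the
  per-column read majority.
* **Truth-side eligibility** applies the marker criteria to the truth table
  (flank distance to gene ends, no neighboring truth variant within 50 bp,
  homopolymer context checked with either allele substituted at the site,
  ≥2 reads per allele given the actual kept-read layout), giving the
  denominator for recall.

What the generator does **not** model: expression-level variation (all genes
are sequenced at the same target coverage), flowgram-level 454 noise,
alternative splicing, indel polymorphism between alleles (alleles differ by
substitutions only; indels enter only as sequencing errors), and assembler
misalignment around repeats.  Passing the recovery tests therefore shows the
pipeline's logic is correct under its stated assumptions, not that any real
assembly is this clean.

## Problem sizes and determinism

The test suite and the acceptance script use 150-gene truth-mode simulations
(~20,000 reads) for parameter recovery, ten 4-gene replicates for chimera
detection, and ≤5-kb databases for oracle-equivalence — sizes chosen so a
full run completes in a few minutes on one CPU while keeping ≥50 eligible
truth markers and ≥20 merged contigs in play.  All randomness flows from a
single integer seed through `numpy.random.default_rng`; identical seeds give
byte-identical reads, assemblies and marker tables.

## Known limitations

* Haplotype counting is parsimony-based; when column blocks are unlinked by
  a monomorphic stretch longer than the read length, fragments merge by
  compatibility and the count can fall below the true number of alleles
  (never above, which is the direction the chimera test cares about).
* The D-value normalization is one concrete choice among several the verbal
  definition admits; use it comparatively, not across tools.
* E-values mimic ungapped BLASTN statistics applied to gapped scores; they
  order hits correctly and reproduce threshold decisions on ≥90%-identity
  hits, but are not calibrated p-values for heavily gapped alignments.
* The uniqueness screen can only see paralogs that were assembled; a paralog
  whose reads were left as singletons is invisible to it.
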