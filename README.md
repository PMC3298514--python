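# snpmine

SNP-marker mining from de novo transcriptome assemblies of highly
heterozygous, non-model species.

## The problem

Outbreeding species with large genomes and no reference sequence (lily,
onion, many ornamentals and trees) are typical targets for transcriptome
(EST) sequencing followed by SNP marker development for genetic mapping.
Two properties of such data make naive SNP calling unreliable:

* **High heterozygosity** — roughly one polymorphic site per 30 bp between
  genotypes and one heterozygous site per 50 bp within a genotype — confuses
  de novo assemblers: overlap-layout assemblers tend to split the alleles of
  one locus into several contigs (redundancy), while k-mer-graph assemblers
  tend to swallow paralogous gene copies into one chimeric contig.
* **Clonal duplicate reads** (PCR/emulsion-PCR artifacts, here ~35% of the
  library) double-count single molecules, turning lone polymerase errors
  into apparently well-supported variants.

`snpmine` implements the complete marker-retrieval flow around an external
assembly:

1. **preprocess** — barcode demultiplexing (exact 6-nt match), adapter
   removal, modified-Mott quality trimming at an error-probability limit of
   0.05, fixed terminal trimming (1 bp at 5', 15 bp at 3'), ambiguity (max
   2 N) and length (100–800 bp) gates.
2. **dedup** — clonal-read removal: greedy clustering of reads sharing their
   first 6 bases at ≥98% prefix-anchored identity over the shorter read;
   only the longest member of each cluster is kept.
3. **snpcall** — on imported contig alignments (ACE or SAM): a column is a
   *potential SNP* if ≥2 distinct bases each have ≥2 supporting reads; reads
   are phased into haplotypes over those columns; a potential SNP becomes a
   *reliable marker* only with 50 bp of SNP/indel-free flank on each side,
   clear of homopolymer tracts, in high-quality sequence.  The **quality
   D-value** (standard deviation of the normalized per-haplotype divergence
   counts) and the **haplotype ceiling** (genotypes × ploidy; 8 for four
   diploids) diagnose chimeric paralog-mixing contigs, which yield no
   markers.
4. **unique** — each marker's 101-bp flank (SNP at position 51) is searched
   against *all* contigs of the same assembly with a seed-and-extend
   aligner using Karlin–Altschul statistics (E = m·n·2^(−S′)); a marker is
   kept only if its sole hit at E ≤ 1e-20 is its own source contig.
5. **assemblycmp** — per-assembly statistics (contigs, lengths, reads per
   contig), transcriptome-coverage estimates, and contig-vs-contig
   redundancy histograms for comparing two assemblies of the same reads.
6. **simdata** — a synthetic-data generator with full truth tables (shared
   polymorphic sites, paralogs, 454-like reads with homopolymer indel
   errors, clonal duplicates, barcodes) so every stage is testable without
   any sequencing data.

## Worked example

Generate a small synthetic experiment (4 diploid genotypes, 6 genes, 35%
clonal reads) and run the whole flow:

```bash
snpmine simulate --seed 21 --n-genes 6 --outdir sim
cat > run.yaml <<EOF
sim:
  seed: 21
  n_genes: 6
sim_mode: truth
EOF
snpmine run --config run.yaml --outdir out
```

which prints:

```
input reads:          4,258
cleaned reads:        4,256 (rejected 0.0%)
after dedup:          2,767 (clonal 35.0%)
contigs:              6
potential SNPs:       146
reliable markers:     3
unique markers:       3
```

Reading the report: of 4,258 simulated reads, 2 failed the length gate;
35.0% were removed as clonal duplicates (the generator planted 35%); the six
truth-mode contigs contain 146 well-supported polymorphic columns, but only
3 of them have the clean 101-bp context an array assay needs — and all 3 map
uniquely back to their own contig, so all 3 survive as markers.
`out/markers.tsv` carries the full records (alleles, intra/inter class,
D-value, haplotype count, filter ledger) and `out/markers.fasta` the 101-bp
flanks with the SNP as an IUPAC code at base 51.

The same subcommands work on real data: `snpmine preprocess`, `snpmine
dedup`, `snpmine snpcall consensus.fasta alignment.ace`, `snpmine unique`,
`snpmine compare` (see `--help` for each).

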