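"""Synthetic transcriptome, read and assembly generator with full truth tables.

Emulates the statistical structure of a multi-genotype EST pyrosequencing
experiment on a highly heterozygous outbreeding diploid: four barcoded
genotypes, within-genotype heterozygosity of about one SNP per 50 bp,
between-genotype polymorphism of about one SNP per 30 bp, a fraction of
duplicated (paralogous) gene copies, 454-like read lengths (mean 283 bp after
trimming), homopolymer-associated indel errors, and ~35% clonal duplicate
reads.  Every emitted read maps to exactly one truth row, so each pipeline
stage can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import edlib
import numpy as np

from snpmine.seqio import (
    AlignmentRow,
    ContigAlignment,
    Read,
    build_padded_alignment,
    phred_to_error,
)

BASES = np.array(list("ACGT"))

DEFAULT_BARCODES = {
    "g1": "ACGTAC",
    "g2": "TGCATG",
    "g3": "GATCGA",
    "g4": "CTAGCT",
}


@dataclass
class SimConfig:
    """Study-condition parameters for the generator.

    Rates are per bp; ``coverage`` is mean read depth per allele copy.
    ``clonal_rate`` is the fraction of the final read set that consists of
    duplicates (the removable fraction).
    """

    seed: int
    n_genes: int = 50
    gene_length_mean: int = 800
    gene_length_sd: int = 150
    gene_length_min: int = 400
    paralog_fraction: float = 0.0
    paralog_divergence: float = 0.05
    n_genotypes: int = 4
    ploidy: int = 2
    intra_snp_rate: float = 1 / 50
    inter_snp_rate: float = 1 / 30
    read_length_mean: int = 283
    read_length_sd: int = 40
    read_length_min: int = 120
    coverage: float = 20.0
    homopolymer_error_rate: float = 0.0
    clonal_rate: float = 0.35
    base_quality: int = 40
    barcodes: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_BARCODES))

    def __post_init__(self) -> None:
        for r in (
            self.paralog_fraction,
            self.paralog_divergence,
            self.intra_snp_rate,
            self.inter_snp_rate,
            self.homopolymer_error_rate,
            self.clonal_rate,
        ):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        if len(self.barcodes) < self.n_genotypes:
            raise ValueError("need a barcode per genotype")

    @property
    def genotypes(self) -> list[str]:
        return list(self.barcodes)[: self.n_genotypes]


@dataclass
class TruthVariant:
    position: int  # 1-based on the gene
    ref: str
    alt: str
    kind: str  # "intra" | "inter"
    genotypes: list[str]  # genotypes affected (het for intra, alt-fixed for inter)


@dataclass
class Gene:
    id: str
    ancestral: str
    alleles: dict[str, list[str]]  # genotype -> one sequence per haploid copy
    variants: list[TruthVariant] = field(default_factory=list)
    paralog_of: str | None = None

    @property
    def length(self) -> int:
        return len(self.ancestral)


@dataclass
class ReadTruth:
    gene: str
    genotype: str
    hap: int
    start: int  # 0-based on the gene
    clonal_parent: str | None = None


@dataclass
class Transcriptome:
    config: SimConfig
    genes: list[Gene]
    read_truth: dict[str, ReadTruth] = field(default_factory=dict)

    def gene_by_id(self) -> dict[str, Gene]:
        return {g.id: g for g in self.genes}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _mutate_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


def simulate_transcriptome(config: SimConfig, rng: np.random.Generator | None = None) -> Transcriptome:
    """Draw gene sequences and per-genotype alleles with truth variants.

    Ancestral genes are i.i.d. uniform over ACGT.  Between-genotype variants
    are placed per-bp at ``inter_snp_rate`` and each genotype is fixed for one
    of the two alleles; within-genotype variants are placed per genotype at
    ``intra_snp_rate`` and make that genotype heterozygous.  Paralogs duplicate
    a parent gene and diverge at ``paralog_divergence`` per bp.
    """
    rng = rng or np.random.default_rng(config.seed)
    genotypes = config.genotypes
    genes: list[Gene] = []

    n_paralogs = int(round(config.n_genes * config.paralog_fraction))
    ancestors: list[tuple[str, str, str | None]] = []
    for i in range(config.n_genes):
        length = max(
            config.gene_length_min,
            int(rng.normal(config.gene_length_mean, config.gene_length_sd)),
        )
        ancestors.append((f"gene{i:04d}", _random_seq(rng, length), None))
    for j in range(n_paralogs):
        parent_id, parent_seq, _ = ancestors[j % config.n_genes]
        seq = list(parent_seq)
        for pos in np.nonzero(rng.random(len(seq)) < config.paralog_divergence)[0]:
            seq[pos] = _mutate_base(rng, seq[pos])
        ancestors.append((f"gene{config.n_genes + j:04d}", "".join(seq), parent_id))

    # Polymorphic sites are shared across the breeding pool: the between-
    # genotype rate is the total segregating-site density, and at each site a
    # genotype is heterozygous with probability intra_rate / inter_rate (so the
    # within-genotype heterozygous density comes out at intra_snp_rate).
    p_het = min(1.0, config.intra_snp_rate / config.inter_snp_rate) if config.inter_snp_rate else 0.0

    for gene_id, ancestral, paralog_of in ancestors:
        L = len(ancestral)
        variants: list[TruthVariant] = []
        allele_chars: dict[str, list[list[str]]] = {
            g: [list(ancestral) for _ in range(config.ploidy)] for g in genotypes
        }
        site_mask = rng.random(L) < config.inter_snp_rate if config.inter_snp_rate else np.zeros(L, dtype=bool)
        if config.intra_snp_rate and not config.inter_snp_rate:
            site_mask = rng.random(L) < config.intra_snp_rate
            p_het_local = 1.0
        else:
            p_het_local = p_het
        for pos in np.nonzero(site_mask)[0]:
            ref = ancestral[pos]
            alt = _mutate_base(rng, ref)
            het_genos: list[str] = []
            alt_fixed: list[str] = []
            ref_fixed: list[str] = []
            for g in genotypes:
                u = rng.random()
                if u < p_het_local:
                    het_genos.append(g)
                    het_copy = int(rng.integers(0, config.ploidy))
                    allele_chars[g][het_copy][pos] = alt
                elif u < p_het_local + (1 - p_het_local) / 2:
                    alt_fixed.append(g)
                    for c in allele_chars[g]:
                        c[pos] = alt
                else:
                    ref_fixed.append(g)
            if not het_genos and (not alt_fixed or not ref_fixed):
                # monomorphic draw: revert
                for g in alt_fixed:
                    for c in allele_chars[g]:
                        c[pos] = ref
                continue
            if het_genos:
                kind = "intra"
                affected = het_genos
            else:
                kind = "inter"
                affected = alt_fixed
            variants.append(
                TruthVariant(position=int(pos) + 1, ref=ref, alt=alt, kind=kind, genotypes=affected)
            )
        variants.sort(key=lambda v: v.position)
        alleles = {g: ["".join(c) for c in copies] for g, copies in allele_chars.items()}
        genes.append(
            Gene(id=gene_id, ancestral=ancestral, alleles=alleles, variants=variants, paralog_of=paralog_of)
        )
    return Transcriptome(config=config, genes=genes)


def _apply_homopolymer_errors(rng: np.random.Generator, bases: str, rate: float) -> str:
    """Insert or delete one base at homopolymer runs (>= 3) with the given rate."""
    if rate <= 0:
        return bases
    out: list[str] = []
    i = 0
    n = len(bases)
    while i < n:
        j = i
        while j < n and bases[j] == bases[i]:
            j += 1
        run = bases[i:j]
        if j - i >= 3 and rng.random() < rate:
            if rng.random() < 0.5:
                run = run + bases[i]  # insertion
            else:
                run = run[:-1]  # deletion
        out.append(run)
        i = j
    return "".join(out)


def simulate_reads(
    transcriptome: Transcriptome, rng: np.random.Generator | None = None
) -> list[Read]:
    """Draw barcoded 454-like reads from the allele sequences.

    Read starts are sampled without replacement within each gene (random-primed
    fragments), so independent reads never coincide exactly; clonal duplicates
    are then added as (possibly truncated) copies of existing reads until they
    make up ``clonal_rate`` of the output.  Provenance is recorded in
    ``transcriptome.read_truth``; read ids are ``<genotype>_<serial>`` so the
    genotype is recoverable from the default read-name pattern.
    """
    cfg = transcriptome.config
    rng = rng or np.random.default_rng(cfg.seed + 1)
    reads: list[Read] = []
    serial = 0
    for gene in transcriptome.genes:
        L = gene.length
        max_start = L - cfg.read_length_min
        if max_start < 1:
            continue
        per_allele = max(1, int(round(cfg.coverage * L / cfg.read_length_mean)))
        n_total = per_allele * cfg.n_genotypes * cfg.ploidy
        replace_starts = n_total > max_start
        starts = rng.choice(max_start, size=n_total, replace=replace_starts)
        k = 0
        for g in cfg.genotypes:
            for hap in range(cfg.ploidy):
                allele = gene.alleles[g][hap]
                for _ in range(per_allele):
                    start = int(starts[k])
                    k += 1
                    length = int(rng.normal(cfg.read_length_mean, cfg.read_length_sd))
                    length = max(cfg.read_length_min, length)
                    length = min(length, L - start)
                    fragment = allele[start : start + length]
                    fragment = _apply_homopolymer_errors(rng, fragment, cfg.homopolymer_error_rate)
                    read_id = f"{g}_{serial:06d}"
                    serial += 1
                    bases = cfg.barcodes[g] + fragment
                    reads.append(
                        Read(
                            id=read_id,
                            bases=bases,
                            quals=[phred_to_error(cfg.base_quality)] * len(bases),
                            genotype=g,
                        )
                    )
                    transcriptome.read_truth[read_id] = ReadTruth(
                        gene=gene.id, genotype=g, hap=hap, start=start
                    )
    # clonal duplicates: n_dup / (n_base + n_dup) == clonal_rate
    if cfg.clonal_rate > 0 and reads:
        n_base = len(reads)
        n_dup = int(round(n_base * cfg.clonal_rate / (1 - cfg.clonal_rate)))
        parents = rng.integers(0, n_base, size=n_dup)
        for pi in parents:
            parent = reads[int(pi)]
            truth = transcriptome.read_truth[parent.id]
            # truncate up to 10% so the longest member is the original
            cut = int(rng.integers(0, max(1, len(parent.bases) // 10)))
            end = len(parent.bases) - cut
            read_id = f"{parent.genotype}_{serial:06d}"
            serial += 1
            reads.append(
                Read(
                    id=read_id,
                    bases=parent.bases[:end],
                    quals=parent.quals[:end] if parent.quals else None,
                    genotype=parent.genotype,
                )
            )
            transcriptome.read_truth[read_id] = replace(truth, clonal_parent=parent.id)
    return reads


# ---------------------------------------------------------------------------
# assembly emulation
# ---------------------------------------------------------------------------


def _place_read(bases: str, allele: str) -> tuple[int, list[tuple[str, int, int, str]]]:
    """Alignment events of a (possibly trimmed/error-bearing) read on its gene."""
    res = edlib.align(bases, allele, mode="HW", task="path")
    start = res["locations"][0][0]
    events: list[tuple[str, int, int, str]] = []
    qi, ref = 0, start
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        ln = int(num)
        num = ""
        if ch in ("=", "X", "M"):
            events.append(("M", ref, ln, bases[qi : qi + ln]))
            ref += ln
            qi += ln
        elif ch == "I":
            events.append(("I", ref - 1, ln, bases[qi : qi + ln]))
            qi += ln
        elif ch == "D":
            events.append(("D", ref, ln, ""))
            ref += ln
    return start, events


def _majority_consensus(alignment: ContigAlignment) -> ContigAlignment:
    """Replace each non-pad consensus base by the column majority among reads."""
    from snpmine.snpcall import column_code_matrix

    if not alignment.members:
        return alignment
    mat = column_code_matrix(alignment)
    counts = np.stack([(mat == b).sum(axis=0) for b in range(4)])  # (4, L)
    majority = counts.argmax(axis=0)  # ties -> lexicographically first base
    covered = counts.sum(axis=0) > 0
    chars = list(alignment.consensus)
    for col in np.nonzero(covered)[0]:
        if chars[col] != "*":
            chars[col] = "ACGT"[majority[col]]
    alignment.consensus = "".join(chars)
    return alignment


def emit_true_assembly(
    transcriptome: Transcriptome,
    reads: list[Read],
    mode: str = "truth",
    split_fraction: float = 0.5,
    rng: np.random.Generator | None = None,
) -> list[ContigAlignment]:
    """Stand-in assembler with controllable failure modes.

    ``truth``: one contig per gene, all alleles co-assembled (the ideal
    single-locus contigs).  ``split``: for ``split_fraction`` of the genes the
    allele copies are split over two contigs, emulating an over-discriminating
    overlap-layout assembler separating divergent alleles.  ``merged``:
    paralog pairs are co-assembled into one chimeric contig, emulating a
    k-mer-graph assembler swallowing paralogs.  Consensus bases are the
    per-column read majority.
    """
    cfg = transcriptome.config
    rng = rng or np.random.default_rng(cfg.seed + 2)
    by_gene: dict[str, list[Read]] = {}
    truth = transcriptome.read_truth
    for r in reads:
        t = truth.get(r.id)
        if t is None:
            raise ValueError(f"read {r.id!r} has no truth row")
        by_gene.setdefault(t.gene, []).append(r)
    genes = transcriptome.gene_by_id()

    def rows_for(rs: list[Read], coord_gene: Gene) -> list[AlignmentRow]:
        rows = []
        for r in rs:
            t = truth[r.id]
            src = genes[t.gene]
            # paralogs share the parent's length, so gene coordinates transfer
            allele = src.alleles[t.genotype][t.hap]
            bases = r.bases
            bc = cfg.barcodes.get(t.genotype, "")
            if bc and bases.startswith(bc):
                bases = bases[len(bc) :]  # raw (untrimmed) reads still carry it
            _start, events = _place_read(bases, allele)
            rows.append((r.id, t.genotype, events))
        return rows

    contigs: list[ContigAlignment] = []
    if mode == "truth":
        for gene in transcriptome.genes:
            rs = by_gene.get(gene.id, [])
            if not rs:
                continue
            aln = build_padded_alignment(gene.id, gene.ancestral, rows_for(rs, gene))
            contigs.append(_majority_consensus(aln))
    elif mode == "split":
        for gene in transcriptome.genes:
            rs = by_gene.get(gene.id, [])
            if not rs:
                continue
            if rng.random() < split_fraction:
                # split the allele copies into two groups
                groups: dict[int, list[Read]] = {0: [], 1: []}
                copy_group = {
                    (g, hap): (hap % 2) for g in cfg.genotypes for hap in range(cfg.ploidy)
                }
                for r in rs:
                    t = truth[r.id]
                    groups[copy_group[(t.genotype, t.hap)]].append(r)
                for part, part_reads in groups.items():
                    if not part_reads:
                        continue
                    aln = build_padded_alignment(
                        f"{gene.id}.{part}", gene.ancestral, rows_for(part_reads, gene)
                    )
                    contigs.append(_majority_consensus(aln))
            else:
                aln = build_padded_alignment(gene.id, gene.ancestral, rows_for(rs, gene))
                contigs.append(_majority_consensus(aln))
    elif mode == "merged":
        merged_children = set()
        for gene in transcriptome.genes:
            if gene.paralog_of:
                merged_children.add(gene.id)
        for gene in transcriptome.genes:
            if gene.id in merged_children:
                continue
            rs = list(by_gene.get(gene.id, []))
            children = [g for g in transcriptome.genes if g.paralog_of == gene.id]
            for child in children:
                rs.extend(by_gene.get(child.id, []))
            if not rs:
                continue
            aln = build_padded_alignment(gene.id, gene.ancestral, rows_for(rs, gene))
            contigs.append(_majority_consensus(aln))
    else:
        raise ValueError(f"unknown assembly mode {mode!r}")
    return contigs


# ---------------------------------------------------------------------------
# truth-side marker eligibility (for scoring the pipeline)
# ---------------------------------------------------------------------------


def _homopolymer_windows(seq: str, min_run: int = 3) -> set[int]:
    """1-based positions inside or adjacent to homopolymer runs >= min_run."""
    out: set[int] = set()
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            out.update(range(i, j + 2))  # 1-based [start, end+1]
        i = j
    return out


def eligible_marker_positions(
    transcriptome: Transcriptome,
    kept_reads: list[Read],
    flank: int = 50,
    min_reads_per_allele: int = 2,
    homopolymer_min: int = 3,
) -> dict[str, set[int]]:
    """Truth variants that meet the marker-reliability criteria, per gene.

    A truth variant is eligible when it has ``flank`` bp to each gene end, no
    other truth variant within ``flank`` bp, sits clear of homopolymer tracts,
    and — given the actual kept-read layout — both alleles are covered by at
    least ``min_reads_per_allele`` reads.
    """
    truth = transcriptome.read_truth
    cover: dict[str, list[tuple[int, int, str, int]]] = {}
    for r in kept_reads:
        t = truth[r.id]
        # post-trim placement: find the read inside its allele
        gene = next(g for g in transcriptome.genes if g.id == t.gene)
        allele = gene.alleles[t.genotype][t.hap]
        res = edlib.align(r.bases, allele, mode="HW", task="locations")
        loc = res["locations"][0]
        cover.setdefault(t.gene, []).append((loc[0], loc[1], t.genotype, t.hap))

    out: dict[str, set[int]] = {}
    for gene in transcriptome.genes:
        positions = [v.position for v in gene.variants]
        eligible: set[int] = set()
        for v in gene.variants:
            p = v.position
            if p <= flank or p > gene.length - flank:
                continue
            if any(q != p and abs(q - p) <= flank for q in positions):
                continue
            # either allele at the site may create or extend a run in the
            # assembled consensus, so both contexts must be clear
            in_homo = False
            for base in (v.ref, v.alt):
                ctx = gene.ancestral[: p - 1] + base + gene.ancestral[p:]
                if p in _homopolymer_windows(ctx, homopolymer_min):
                    in_homo = True
                    break
            if in_homo:
                continue
            # allele support from the actual read layout
            ref_n = alt_n = 0
            for start, end, g, hap in cover.get(gene.id, []):
                if not (start <= p - 1 <= end):
                    continue
                base = gene.alleles[g][hap][p - 1]
                if base == v.alt:
                    alt_n += 1
                elif base == v.ref:
                    ref_n += 1
            if ref_n >= min_reads_per_allele and alt_n >= min_reads_per_allele:
                eligible.add(p)
        out[gene.id] = eligible
    return out


def truth_variant_positions(transcriptome: Transcriptome) -> dict[str, set[int]]:
    """All truth variant positions per gene (1-based)."""
    return {g.id: {v.position for v in g.variants} for g in transcriptome.genes}
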