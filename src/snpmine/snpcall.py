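"""Haplotype-based SNP detection on contig alignments.

A column of the padded contig alignment is a *potential SNP* when at least two
distinct bases are each supported by at least ``min_reads_per_allele`` reads.
Reads are then grouped into haplotypes by their allele vectors over the
potential-SNP columns; the spread of per-haplotype divergence from the
consensus (the quality D-value) and the haplotype count diagnose contigs that
mix paralogous loci with allelic variation.  A potential SNP becomes a marker
only if it sits in high-quality sequence, away from homopolymer tracts, with
50 bp of SNP- and indel-free flank on each side — the requirements of
array-based genotyping assays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from snpmine.seqio import PAD, AlignedMember, ContigAlignment, MarkerRecord

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_CODE[ord("N")] = 4
_CODE[ord(PAD)] = 5


def column_code_matrix(alignment: ContigAlignment) -> np.ndarray:
    """Members x padded-columns matrix: -1 uncovered, 0-3 ACGT, 4 N, 5 pad."""
    n = len(alignment.members)
    L = len(alignment.consensus)
    mat = np.full((n, L), -1, dtype=np.int8)
    for i, m in enumerate(alignment.members):
        arr = np.frombuffer(m.aligned.encode(), dtype=np.uint8)
        mat[i, m.offset : m.end] = _CODE[arr]
    return mat

FAIL_REASONS = ("homopolymer", "dirty_flank", "short_flank", "low_quality", "low_support")


@dataclass
class VariantColumn:
    """One polymorphic (or indel-bearing) column of a contig alignment."""

    contig_id: str
    position: int  # 1-based on the ungapped consensus
    padded_col: int  # internal padded-column index (0-based)
    allele_counts: dict[str, dict[str, int]]  # genotype -> base -> read count
    is_indel_column: bool = False

    def total_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for per_geno in self.allele_counts.values():
            for base, n in per_geno.items():
                out[base] = out.get(base, 0) + n
        return out

    def top_alleles(self) -> tuple[str, str]:
        counts = self.total_counts()
        ranked = sorted(counts, key=lambda b: (-counts[b], b))
        return ranked[0], ranked[1]


@dataclass
class Haplotype:
    id: int
    allele_vector: list[str | None]  # per potential-SNP column; None = unobserved
    member_read_ids: list[str] = field(default_factory=list)
    genotypes: list[str] = field(default_factory=list)
    low_support: bool = False

    @property
    def n_members(self) -> int:
        return len(self.member_read_ids)


@dataclass
class ContigSnpReport:
    contig_id: str
    potential_snp_count: int
    haplotype_count: int
    d_value: float
    chimera_flag: bool = False
    markers: list[MarkerRecord] = field(default_factory=list)
    column_status: list[tuple[int, str, str]] = field(default_factory=list)  # (pos, verdict, reason)


# ---------------------------------------------------------------------------
# variant columns
# ---------------------------------------------------------------------------


def detect_potential_snps(
    alignment: ContigAlignment, min_reads_per_allele: int = 2, per_genotype: bool = False
) -> list[VariantColumn]:
    """Scan every padded column for potential SNPs and indel columns.

    Indel columns (a pad in the consensus or in any covering read) are excluded
    from SNP candidacy but returned flagged, for flank-cleanliness checks.
    Allele support is counted over all genotypes by default; with
    ``per_genotype`` an allele only counts when one genotype alone supplies
    ``min_reads_per_allele`` reads for it.
    """
    if not alignment.members:
        return []
    pos_map = alignment.padded_to_ungapped()
    mat = column_code_matrix(alignment)
    genotypes = [m.genotype for m in alignment.members]
    cons = np.frombuffer(alignment.consensus.encode(), dtype=np.uint8)
    cons_is_pad = cons == ord(PAD)

    base_counts = np.stack([(mat == b).sum(axis=0) for b in range(4)])  # (4, L)
    pad_counts = (mat == 5).sum(axis=0)
    covered = (mat >= 0).sum(axis=0)

    pad_signal = cons_is_pad | (pad_counts >= min_reads_per_allele)
    has_any_pad = cons_is_pad | (pad_counts > 0)
    indel_cols = np.nonzero(pad_signal & (covered > 0))[0]

    if per_genotype:
        geno_set = sorted(set(genotypes))
        rows_by_geno = {g: [i for i, x in enumerate(genotypes) if x == g] for g in geno_set}
        supported = np.zeros((4, mat.shape[1]), dtype=bool)
        for g, rows in rows_by_geno.items():
            sub = mat[rows]
            for b in range(4):
                supported[b] |= (sub == b).sum(axis=0) >= min_reads_per_allele
        n_supported = supported.sum(axis=0)
    else:
        n_supported = (base_counts >= min_reads_per_allele).sum(axis=0)
    snp_cols = np.nonzero(~has_any_pad & (n_supported >= 2))[0]

    def allele_counts_at(col: int) -> dict[str, dict[str, int]]:
        counts: dict[str, dict[str, int]] = {}
        for i, g in enumerate(genotypes):
            b = mat[i, col]
            if b < 0 or b >= 4:
                continue
            counts.setdefault(g, {})
            base = "ACGT"[b]
            counts[g][base] = counts[g].get(base, 0) + 1
        return counts

    columns: list[VariantColumn] = []
    indel_set = set(int(c) for c in indel_cols)
    snp_set = set(int(c) for c in snp_cols)
    for col in sorted(indel_set | snp_set):
        # 1-based ungapped position; pad columns inherit the previous base's
        pos = pos_map[col]
        if pos == 0:
            back = col
            while back >= 0 and pos_map[back] == 0:
                back -= 1
            pos = pos_map[back] if back >= 0 else 1
        columns.append(
            VariantColumn(
                contig_id=alignment.contig_id,
                position=max(pos, 1),
                padded_col=col,
                allele_counts=allele_counts_at(col),
                is_indel_column=col in indel_set,
            )
        )
    return columns


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------


def _read_vector(member: AlignedMember, snp_cols: Sequence[int]) -> list[str | None]:
    vec: list[str | None] = []
    for col in snp_cols:
        if member.offset <= col < member.end:
            b = member.aligned[col - member.offset]
            vec.append(b if b not in (PAD, "N") else None)
        else:
            vec.append(None)
    return vec


def _compatible(hap_vec: Sequence[str | None], read_vec: Sequence[str | None]) -> int:
    """Number of shared defined columns, or -1 on conflict."""
    shared = 0
    for a, b in zip(hap_vec, read_vec):
        if a is None or b is None:
            continue
        if a != b:
            return -1
        shared += 1
    return shared


def reconstruct_haplotypes(
    alignment: ContigAlignment, potential_snps: Sequence[VariantColumn]
) -> list[Haplotype]:
    """Group reads by their allele vectors over the potential-SNP columns.

    Reads covering a subset of columns merge into the unique compatible
    haplotype (sharing at least one defined column); when several haplotypes
    are compatible the read joins the largest rather than founding a new one,
    so that partially informative reads do not inflate the haplotype count.
    Reads covering no potential-SNP column are pooled with the largest
    haplotype (or form the single haplotype of a monomorphic contig).
    """
    snp_cols = [c.padded_col for c in potential_snps if not c.is_indel_column]
    if not snp_cols:
        hap = Haplotype(id=0, allele_vector=[])
        for m in alignment.members:
            hap.member_read_ids.append(m.read_id)
            hap.genotypes.append(m.genotype)
        return [hap] if hap.member_read_ids else []

    vectors = [(m, _read_vector(m, snp_cols)) for m in alignment.members]
    informative = [(m, v) for m, v in vectors if any(x is not None for x in v)]
    uninformative = [m for m, v in vectors if not any(x is not None for x in v)]
    # left-to-right so each read overlaps the already-phased region; widest first
    informative.sort(
        key=lambda mv: (
            next(i for i, x in enumerate(mv[1]) if x is not None),
            -sum(x is not None for x in mv[1]),
            mv[0].read_id,
        )
    )

    haplotypes: list[Haplotype] = []
    for m, vec in informative:
        matches = []
        for h in haplotypes:
            shared = _compatible(h.allele_vector, vec)
            if shared > 0:
                matches.append((shared, h))
        if matches:
            # prefer the haplotype sharing the most defined columns: a short
            # coincidental agreement must not beat the read's own chain
            matches.sort(key=lambda sh: (-sh[0], -sh[1].n_members, sh[1].id))
            target = matches[0][1]
        else:
            target = Haplotype(id=len(haplotypes), allele_vector=[None] * len(snp_cols))
            haplotypes.append(target)
        for i, b in enumerate(vec):
            if b is not None and target.allele_vector[i] is None:
                target.allele_vector[i] = b
        target.member_read_ids.append(m.read_id)
        target.genotypes.append(m.genotype)

    # parsimony pass: chains break where two alleles are locally identical or
    # where a long monomorphic stretch unlinks column blocks; any fragment that
    # is still compatible with another haplotype merges into its best partner
    # (most shared columns, then largest), so the count is the minimum number
    # of haplotypes consistent with the reads
    changed = True
    while changed and len(haplotypes) > 1:
        changed = False
        for h in sorted(haplotypes, key=lambda x: (x.n_members, x.id)):
            partners = []
            for o in haplotypes:
                if o is h:
                    continue
                shared = _compatible(o.allele_vector, h.allele_vector)
                if shared >= 0:
                    partners.append((shared, o))
            if partners:
                partners.sort(key=lambda so: (-so[0], -so[1].n_members, so[1].id))
                o = partners[0][1]
                for i, b in enumerate(h.allele_vector):
                    if b is not None and o.allele_vector[i] is None:
                        o.allele_vector[i] = b
                o.member_read_ids.extend(h.member_read_ids)
                o.genotypes.extend(h.genotypes)
                haplotypes.remove(h)
                changed = True
                break

    if haplotypes:
        biggest = max(haplotypes, key=lambda h: (h.n_members, -h.id))
        for m in uninformative:
            biggest.member_read_ids.append(m.read_id)
            biggest.genotypes.append(m.genotype)
    for h in haplotypes:
        h.low_support = h.n_members < 2
    return haplotypes


def d_value(haplotypes: Sequence[Haplotype], potential_snps: Sequence[VariantColumn]) -> float:
    """Quality D-value: population SD of normalized per-haplotype divergence.

    For each haplotype, count the potential-SNP columns where its allele
    differs from the column's majority allele (read-count majority; ties broken
    toward the largest haplotype's allele), normalize by the number of columns,
    and take the population standard deviation across haplotypes.  High D
    flags contigs mixing paralogs with alleles.
    """
    snp_columns = [c for c in potential_snps if not c.is_indel_column]
    m = len(snp_columns)
    h = len(haplotypes)
    if m == 0 or h <= 1:
        return 0.0
    largest = max(haplotypes, key=lambda x: (x.n_members, -x.id))
    fractions = []
    for hap in haplotypes:
        n_i = 0
        for i, colrec in enumerate(snp_columns):
            allele = hap.allele_vector[i] if i < len(hap.allele_vector) else None
            if allele is None:
                continue
            counts = colrec.total_counts()
            best = max(counts.values())
            top = sorted(b for b, n in counts.items() if n == best)
            if len(top) > 1:
                tie_break = largest.allele_vector[i] if i < len(largest.allele_vector) else None
                majority = tie_break if tie_break in top else top[0]
            else:
                majority = top[0]
            if allele != majority:
                n_i += 1
        fractions.append(n_i / m)
    mean = sum(fractions) / h
    return math.sqrt(sum((f - mean) ** 2 for f in fractions) / h)


# ---------------------------------------------------------------------------
# classification and reliability filtering
# ---------------------------------------------------------------------------


def classify_snp(column: VariantColumn, min_reads_per_allele: int = 2) -> tuple[str, bool]:
    """Classify a potential SNP as within-genotype (intra) or between (inter).

    Returns (class, both_flag).  A column is *intra* when both alleles are
    adequately supported inside a single genotype (heterozygosity), *inter*
    when the alleles segregate between genotypes (one genotype carries only
    allele 1, another only allele 2).  A column showing both patterns reports
    the more informative *inter* class with ``both_flag`` set.
    """
    a1, a2 = column.top_alleles()
    # intra needs evidence of heterozygosity inside one genotype
    intra = any(
        per_geno.get(a1, 0) >= min_reads_per_allele
        and per_geno.get(a2, 0) >= min_reads_per_allele
        for per_geno in column.allele_counts.values()
    )
    only_a1 = [g for g, c in column.allele_counts.items() if c.get(a1, 0) > 0 and c.get(a2, 0) == 0]
    only_a2 = [g for g, c in column.allele_counts.items() if c.get(a2, 0) > 0 and c.get(a1, 0) == 0]
    inter = bool(only_a1) and bool(only_a2)
    if inter:
        return "inter", intra
    return "intra", False


def _homopolymer_runs(seq: str, min_run: int) -> list[tuple[int, int]]:
    """Maximal runs of identical bases of length >= min_run, as 0-based [start, end)."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            runs.append((i, j))
        i = j
    return runs


def filter_reliable(
    column: VariantColumn,
    alignment: ContigAlignment,
    all_columns: Sequence[VariantColumn],
    flank: int = 50,
    homopolymer_min: int = 3,
    min_reads_per_allele: int = 2,
    min_mean_phred: float = 20.0,
    read_quals: dict[str, list[float]] | None = None,
) -> tuple[str, str | None]:
    """Apply the marker-reliability criteria to one potential SNP.

    Returns ("pass", None) or ("fail", reason), with reason one of
    ``homopolymer``, ``dirty_flank``, ``short_flank``, ``low_quality``,
    ``low_support``.
    """
    pos = column.position
    length = alignment.ungapped_length
    if pos <= flank or pos > length - flank:
        return "fail", "short_flank"
    for other in all_columns:
        if other.padded_col == column.padded_col and not other.is_indel_column:
            continue
        if other.position != pos and abs(other.position - pos) <= flank:
            return "fail", "dirty_flank"
        if other.is_indel_column and other.position == pos:
            return "fail", "dirty_flank"
    consensus = alignment.ungapped_consensus
    for start, end in _homopolymer_runs(consensus, homopolymer_min):
        # inside or immediately adjacent (1-based pos vs 0-based [start, end))
        if start <= pos - 1 < end or pos - 1 == start - 1 or pos - 1 == end:
            return "fail", "homopolymer"
    totals = column.total_counts()
    supported = [b for b, n in totals.items() if n >= min_reads_per_allele]
    if len(supported) < 2:
        return "fail", "low_support"
    if read_quals is not None:
        phreds = []
        for m in alignment.members:
            if not (m.offset <= column.padded_col < m.end):
                continue
            q = read_quals.get(m.read_id)
            if q is None:
                continue
            base_idx = sum(
                1
                for c in m.aligned[: column.padded_col - m.offset]
                if c != PAD
            )
            if base_idx < len(q):
                p = max(q[base_idx], 1e-9)
                phreds.append(-10.0 * math.log10(p))
        if phreds and sum(phreds) / len(phreds) < min_mean_phred:
            return "fail", "low_quality"
    return "pass", None


def haplotype_ceiling(n_genotypes: int, ploidy: int = 2) -> int:
    """Maximum distinct haplotypes expected from a clean (single-locus) contig."""
    if n_genotypes < 1 or ploidy < 1:
        raise ValueError("n_genotypes and ploidy must be positive")
    return n_genotypes * ploidy


def flag_chimera(report: ContigSnpReport, ceiling: int, keep_chimeric: bool = False) -> ContigSnpReport:
    """Flag a contig whose haplotype count exceeds the ceiling; drop its markers."""
    report.chimera_flag = report.haplotype_count > ceiling
    for m in report.markers:
        m.status.append(("chimera", "fail" if report.chimera_flag else "pass"))
    if report.chimera_flag and not keep_chimeric:
        report.markers = []
    return report


def extract_marker(
    alignment: ContigAlignment,
    column: VariantColumn,
    snp_class: str,
    d: float,
    haplotype_count: int,
    marker_id: str | None = None,
) -> MarkerRecord:
    """Build the 101-bp marker record for a column that passed all filters."""
    pos = column.position
    consensus = alignment.ungapped_consensus
    if pos <= 50 or pos > len(consensus) - 50:
        raise ValueError("marker extraction requires 50 bp of flank on each side")
    flank = consensus[pos - 51 : pos + 50]
    assert len(flank) == 101
    a1, a2 = column.top_alleles()
    return MarkerRecord(
        marker_id=marker_id or f"{alignment.contig_id}:{pos}",
        contig_id=alignment.contig_id,
        position=pos,
        alleles=(a1, a2),
        snp_class=snp_class,
        d_value=d,
        haplotype_count=haplotype_count,
        flank_seq=flank,
        status=[("reliable", "pass")],
    )


def call_contig(
    alignment: ContigAlignment,
    min_reads_per_allele: int = 2,
    flank: int = 50,
    homopolymer_min: int = 3,
    n_genotypes: int = 4,
    ploidy: int = 2,
    keep_chimeric: bool = False,
    read_quals: dict[str, list[float]] | None = None,
    min_mean_phred: float = 20.0,
) -> ContigSnpReport:
    """Run the full per-contig flow: detect, phase, filter, flag, emit markers."""
    columns = detect_potential_snps(alignment, min_reads_per_allele)
    snp_columns = [c for c in columns if not c.is_indel_column]
    haplotypes = reconstruct_haplotypes(alignment, columns)
    d = d_value(haplotypes, columns)
    report = ContigSnpReport(
        contig_id=alignment.contig_id,
        potential_snp_count=len(snp_columns),
        haplotype_count=len(haplotypes),
        d_value=d,
    )
    for col in snp_columns:
        verdict, reason = filter_reliable(
            col,
            alignment,
            columns,
            flank=flank,
            homopolymer_min=homopolymer_min,
            min_reads_per_allele=min_reads_per_allele,
            min_mean_phred=min_mean_phred,
            read_quals=read_quals,
        )
        report.column_status.append((col.position, verdict, reason or ""))
        if verdict == "pass":
            snp_class, _both = classify_snp(col, min_reads_per_allele)
            report.markers.append(
                extract_marker(alignment, col, snp_class, d, len(haplotypes))
            )
    flag_chimera(report, haplotype_ceiling(n_genotypes, ploidy), keep_chimeric)
    return report
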