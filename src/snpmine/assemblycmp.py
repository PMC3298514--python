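"""Assembly-quality statistics and cross-assembly redundancy reporting.

Two de novo assemblies of the same read set can be compared without a
reference: per-assembly summary statistics (contig counts, lengths, reads per
contig), a transcriptome-coverage estimate against a reference monocot gene
complement, and reciprocal contig-vs-contig search to measure redundancy
(several contigs deriving from the same locus).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from snpmine.seqio import ContigAlignment
from snpmine.unique import ScoringParams, SearchHit, build_index, search

LENGTH_BINS = ("<200", "200-999", "1000-1999", ">=2000")


@dataclass
class AssemblyStats:
    n_contigs: int
    mean_length: float
    total_bases: int
    n_assembled_reads: int
    n_singletons: int
    mean_reads_per_contig: float
    length_histogram: dict[str, int]
    max_length: int
    n50: int  # beyond the standard bins; extra convenience field
    n_contigs_all_genotypes: int


def _n50(lengths: Sequence[int]) -> int:
    total = sum(lengths)
    acc = 0
    for ln in sorted(lengths, reverse=True):
        acc += ln
        if acc * 2 >= total:
            return ln
    return 0


def _length_bin(ln: int) -> str:
    if ln < 200:
        return "<200"
    if ln < 1000:
        return "200-999"
    if ln < 2000:
        return "1000-1999"
    return ">=2000"


def assembly_stats(
    contig_alignments: Sequence[ContigAlignment], unassembled_read_count: int = 0
) -> AssemblyStats:
    """Per-assembly summary statistics (contig counts, lengths, reads/contig)."""
    lengths = [a.ungapped_length for a in contig_alignments]
    n = len(lengths)
    total = sum(lengths)
    n_reads = sum(len(a.members) for a in contig_alignments)
    hist = {b: 0 for b in LENGTH_BINS}
    for ln in lengths:
        hist[_length_bin(ln)] += 1
    all_genotype_count = 0
    genotype_universe = set()
    for a in contig_alignments:
        genotype_universe.update(m.genotype for m in a.members)
    for a in contig_alignments:
        if genotype_universe and {m.genotype for m in a.members} == genotype_universe:
            all_genotype_count += 1
    return AssemblyStats(
        n_contigs=n,
        mean_length=round(total / n, 2) if n else 0.0,
        total_bases=total,
        n_assembled_reads=n_reads,
        n_singletons=unassembled_read_count,
        mean_reads_per_contig=round(n_reads / n, 2) if n else 0.0,
        length_histogram=hist,
        max_length=max(lengths) if lengths else 0,
        n50=_n50(lengths),
        n_contigs_all_genotypes=all_genotype_count,
    )


def coverage_estimate(
    total_bases: int, ref_gene_count: int = 41_000, ref_mean_gene_len: int = 2_000
) -> int:
    """Transcriptome coverage as a percent of a reference gene complement.

    The default reference is the rice transcriptome: 41,000 genes of 2,000 bp
    mean length.
    """
    if total_bases < 0 or ref_gene_count <= 0 or ref_mean_gene_len <= 0:
        raise ValueError("inputs must be positive")
    return int(round(100.0 * total_bases / (ref_gene_count * ref_mean_gene_len)))


def _is_trivial_self_hit(query_id: str, query_len: int, h: SearchHit) -> bool:
    return (
        h.contig_id == query_id
        and h.strand == "+"
        and h.identity > 0.99
        and abs(h.contig_start - h.query_start) < 5
    )


def redundancy_report(
    contigs_a: dict[str, str],
    contigs_b: dict[str, str],
    threshold: float = 1e-20,
    word_size: int = 11,
    params: ScoringParams | None = None,
    self_mode: bool | None = None,
) -> dict:
    """Search every contig of A against an index of B; histogram the hit counts.

    In self-mode (A compared against itself) the trivial identity hit of each
    contig on itself is excluded.  The unique fraction is the share of A
    contigs with exactly one above-threshold hit.
    """
    if not contigs_a or not contigs_b:
        raise ValueError("both contig sets must be non-empty")
    if self_mode is None:
        self_mode = contigs_a is contigs_b or contigs_a == contigs_b
    index = build_index(contigs_b, word_size=word_size)
    bins = {"0": 0, "1": 0, "2-5": 0, "6-10": 0, ">10": 0}
    hits_per_contig: dict[str, int] = {}
    all_hits: dict[str, list[SearchHit]] = {}
    for cid, seq in contigs_a.items():
        hits = [h for h in search(seq, index, query_id=cid, params=params) if h.e_value <= threshold]
        if self_mode:
            hits = [h for h in hits if not _is_trivial_self_hit(cid, len(seq), h)]
        all_hits[cid] = hits
        n = len(hits)
        hits_per_contig[cid] = n
        if n == 0:
            bins["0"] += 1
        elif n == 1:
            bins["1"] += 1
        elif n <= 5:
            bins["2-5"] += 1
        elif n <= 10:
            bins["6-10"] += 1
        else:
            bins[">10"] += 1
    total = len(contigs_a)
    n_unique = bins["1"]
    return {
        "bins": bins,
        "hits_per_contig": hits_per_contig,
        "hits": all_hits,
        "n_queries": total,
        "unique_fraction": n_unique / total if total else 0.0,
        "unique_pct": round(n_unique / total * 100, 1) if total else 0.0,
    }


def split_vs_adjacent(
    hits_on_reference: Sequence[SearchHit], min_overlap: int = 20
) -> dict[str, str]:
    """Classify references with >= 2 hits as redundantly overlapping or tiling.

    Multiple contigs matching the same reference can either cover the same
    stretch (redundancy) or tile adjacent stretches (fragmented but unique
    assembly).  References with a single hit are left unclassified.
    """
    by_ref: dict[str, list[SearchHit]] = {}
    for h in hits_on_reference:
        by_ref.setdefault(h.contig_id, []).append(h)
    out: dict[str, str] = {}
    for ref, hits in by_ref.items():
        if len(hits) < 2:
            continue
        overlapping = False
        for i in range(len(hits)):
            for j in range(i + 1, len(hits)):
                a, b = hits[i], hits[j]
                ov = min(a.contig_end, b.contig_end) - max(a.contig_start, b.contig_start) + 1
                if ov >= min_overlap:
                    overlapping = True
        out[ref] = "overlapping" if overlapping else "adjacent"
    return out
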