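"""End-to-end marker retrieval: clean, deduplicate, call, screen, report.

The flow is: preprocess (barcode/adapter/quality trimming) -> clonal-read
removal -> assembly import (external assembler output, or the synthetic
stand-in) -> haplotype-based SNP calling with reliability filters -> chimera
filter -> flank-uniqueness screen -> marker artifacts plus a machine-readable
run report.  Assembly itself is an external stage by design: the method's
point is that marker quality depends on the assembler, so the pipeline only
records assembler provenance as metadata.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from snpmine import dedup as dedup_mod
from snpmine import seqio, simdata, snpcall, unique
from snpmine.preprocess import TrimParams, preprocess_reads

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # external inputs
    reads_path: str | None = None
    reads_format: str = "fastq"
    consensus_path: str | None = None
    alignment_path: str | None = None
    # or synthetic inputs
    sim: simdata.SimConfig | None = None
    sim_mode: str = "truth"
    # stage parameters
    trim: TrimParams = field(default_factory=TrimParams)
    dedup_prefix_len: int = 6
    dedup_min_identity: float = 0.98
    min_reads_per_allele: int = 2
    flank: int = 50
    homopolymer_min: int = 3
    n_genotypes: int = 4
    ploidy: int = 2
    keep_chimeric: bool = False
    unique_threshold: float = 1e-20
    word_size: int = 11
    # provenance metadata only; assembly is external
    assembler: str = "external"
    assembler_params: str = ""
    outdir: str | None = None


def stage_report(counts: dict[str, Any]) -> dict:
    """Render stage counts with percentages (1 decimal; 'n/a' on zero denominators)."""
    n_in = counts.get("input_reads", 0)
    cleaned = counts.get("cleaned_reads", 0)
    dedupped = counts.get("deduplicated_reads", 0)

    def pct(num: int, den: int) -> float | str:
        return round(num / den * 100, 1) if den else "n/a"

    report = dict(counts)
    report["rejected_pct"] = pct(n_in - cleaned, n_in)
    report["clonal_pct"] = pct(cleaned - dedupped, cleaned)
    lines = [
        f"input reads:          {n_in:,}",
        f"cleaned reads:        {cleaned:,} (rejected {report['rejected_pct']}%)",
        f"after dedup:          {dedupped:,} (clonal {report['clonal_pct']}%)",
        f"contigs:              {counts.get('n_contigs', 0):,}",
        f"potential SNPs:       {counts.get('potential_snps', 0):,}",
        f"reliable markers:     {counts.get('reliable_markers', 0):,}",
        f"unique markers:       {counts.get('unique_markers', 0):,}",
    ]
    report["text"] = "\n".join(lines)
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full flow; returns the run report (and writes artifacts).

    Stage-count conservation is asserted on every run: cleaned = input - sum of
    rejections, deduplicated = cleaned - clonal removals.
    """
    transcriptome = None
    if config.sim is not None:
        transcriptome = simdata.simulate_transcriptome(config.sim)
        raw_reads = simdata.simulate_reads(transcriptome)
        trim = config.trim
        if not trim.barcodes:
            trim = TrimParams(**{**trim.__dict__, "barcodes": dict(config.sim.barcodes)})
    elif config.reads_path is not None:
        raw_reads = list(seqio.read_sequences(config.reads_path, config.reads_format))
        trim = config.trim
    else:
        raw_reads = []
        trim = config.trim

    kept, rejected, pre_report = preprocess_reads(raw_reads, trim)
    assert len(kept) + len(rejected) == len(raw_reads)

    deduped, dedup_report = dedup_mod.deduplicate(
        kept, prefix_len=config.dedup_prefix_len, min_identity=config.dedup_min_identity
    )
    assert len(deduped) + dedup_report["removed_reads"] == len(kept)

    if transcriptome is not None:
        contigs = simdata.emit_true_assembly(transcriptome, deduped, mode=config.sim_mode)
    elif config.consensus_path is not None and config.alignment_path is not None:
        contigs = list(seqio.read_assembly(config.consensus_path, config.alignment_path))
    else:
        contigs = []

    quals_by_read = {r.id: r.quals for r in deduped if r.quals is not None}
    reports = []
    candidates: list[seqio.MarkerRecord] = []
    potential = 0
    for aln in contigs:
        rep = snpcall.call_contig(
            aln,
            min_reads_per_allele=config.min_reads_per_allele,
            flank=config.flank,
            homopolymer_min=config.homopolymer_min,
            n_genotypes=config.n_genotypes,
            ploidy=config.ploidy,
            keep_chimeric=config.keep_chimeric,
            read_quals=quals_by_read or None,
        )
        reports.append(rep)
        potential += rep.potential_snp_count
        candidates.extend(rep.markers)

    contig_seqs = {a.contig_id: a.ungapped_consensus for a in contigs}
    if contig_seqs and candidates:
        retained, discard_ledger, histogram = unique.screen_markers(
            candidates,
            contig_seqs,
            threshold=config.unique_threshold,
            word_size=config.word_size,
        )
    else:
        retained, discard_ledger, histogram = [], [], {"bins": {}, "n_markers": 0, "unique_fraction": 0.0, "unique_pct": 0.0}

    counts = {
        "input_reads": len(raw_reads),
        "cleaned_reads": len(kept),
        "deduplicated_reads": len(deduped),
        "n_contigs": len(contigs),
        "potential_snps": potential,
        "reliable_markers": len(candidates),
        "chimeric_contigs": sum(1 for r in reports if r.chimera_flag),
        "unique_markers": len(retained),
    }
    report = stage_report(counts)
    report["preprocess"] = pre_report
    report["dedup"] = {k: v for k, v in dedup_report.items() if k != "removals"}
    report["unique_histogram"] = histogram
    report["discards"] = discard_ledger
    report["parameters"] = {
        "trim": {k: v for k, v in trim.__dict__.items()},
        "dedup_prefix_len": config.dedup_prefix_len,
        "dedup_min_identity": config.dedup_min_identity,
        "min_reads_per_allele": config.min_reads_per_allele,
        "flank": config.flank,
        "homopolymer_min": config.homopolymer_min,
        "haplotype_ceiling": snpcall.haplotype_ceiling(config.n_genotypes, config.ploidy),
        "unique_threshold": config.unique_threshold,
        "word_size": config.word_size,
        "assembler": config.assembler,
        "assembler_params": config.assembler_params,
    }
    report["markers"] = retained
    report["contig_reports"] = reports

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        seqio.write_markers(retained, outdir / "markers.tsv", outdir / "markers.fasta")
        with open(outdir / "contigs.tsv", "w") as fh:
            fh.write("contig_id\tpotential_snps\thaplotypes\td_value\tchimera\n")
            for r in reports:
                fh.write(
                    f"{r.contig_id}\t{r.potential_snp_count}\t{r.haplotype_count}"
                    f"\t{r.d_value:.4f}\t{int(r.chimera_flag)}\n"
                )
        serializable = {
            k: v for k, v in report.items() if k not in ("markers", "contig_reports")
        }
        with open(outdir / "report.json", "w") as fh:
            json.dump(serializable, fh, indent=2)
    return report
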