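import numpy as np
import pytest

from snpmine.dedup import deduplicate
from snpmine.preprocess import TrimParams, preprocess_reads
from snpmine.simdata import SimConfig, emit_true_assembly, simulate_reads, simulate_transcriptome


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def pipeline_run():
    from snpmine.pipeline import PipelineConfig, run_pipeline

    return run_pipeline(PipelineConfig(sim=SimConfig(seed=303, n_genes=10)))


@pytest.fixture(scope="session")
def small_sim():
    """A modest 4-genotype simulation with clonal duplicates, processed to
    deduplicated reads and truth-mode contigs."""
    cfg = SimConfig(seed=202, n_genes=12, clonal_rate=0.35)
    tr = simulate_transcriptome(cfg)
    reads = simulate_reads(tr)
    kept, rejected, report = preprocess_reads(reads, TrimParams(barcodes=dict(cfg.barcodes)))
    deduped, dedup_report = deduplicate(kept)
    contigs = emit_true_assembly(tr, deduped, mode="truth")
    return {
        "config": cfg,
        "transcriptome": tr,
        "raw_reads": reads,
        "kept": kept,
        "rejected": rejected,
        "preprocess_report": report,
        "deduped": deduped,
        "dedup_report": dedup_report,
        "contigs": contigs,
    }
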