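"""Read cleaning: barcode demultiplexing, adapter removal, quality and terminal trimming.

The trimming contract mirrors standard 454 amplicon pre-processing: strip the
6-nt barcode, remove adapter remnants, trim low-quality ends with the modified
Mott running-sum algorithm at an error-probability limit, cut fixed terminal
bases (the first 5' base and the last 15 3' bases, where 454 quality decays),
then gate on ambiguity (max 2 N) and length (100-800 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib

from snpmine.seqio import Read

REJECTION_REASONS = (
    "no_barcode",
    "too_short",
    "too_long",
    "too_many_ambiguous",
    "empty_after_trim",
)


@dataclass
class TrimParams:
    """Trimming thresholds; defaults follow common 454 EST pre-processing practice.

    ``quality_limit`` is an error probability: bases with p above the limit
    count against the Mott running sum.
    """

    quality_limit: float = 0.05
    max_ambiguous: int = 2
    head_trim: int = 1
    tail_trim: int = 15
    min_len: int = 100
    max_len: int = 800
    adapters: list[str] = field(default_factory=list)
    barcodes: dict[str, str] = field(default_factory=dict)
    adapter_min_len: int = 10
    adapter_min_identity: float = 0.9

    def __post_init__(self) -> None:
        if not 0 < self.quality_limit < 1:
            raise ValueError("quality_limit must be in (0, 1)")
        if self.min_len >= self.max_len:
            raise ValueError("min_len must be < max_len")
        bcs = list(self.barcodes.values())
        if any(len(b) != 6 for b in bcs):
            raise ValueError("all barcodes must be 6 nt")
        if len(set(bcs)) != len(bcs):
            raise ValueError("barcodes must be mutually distinct")


@dataclass
class Rejection:
    read_id: str
    reason: str


def mott_trim_interval(error_probs: Sequence[float], limit: float) -> tuple[int, int]:
    """Modified-Mott quality trimming: the maximal running-sum segment.

    Each base scores ``limit - p``; the kept region is the contiguous segment
    maximising the cumulative score (Kadane).  Returns a half-open [start, end)
    interval; (0, 0) when every segment scores non-positive.
    """
    best_sum = 0.0
    best = (0, 0)
    cur_sum = 0.0
    cur_start = 0
    for i, p in enumerate(error_probs):
        cur_sum += limit - p
        if cur_sum <= 0:
            cur_sum = 0.0
            cur_start = i + 1
        elif cur_sum > best_sum:
            best_sum = cur_sum
            best = (cur_start, i + 1)
    return best


def _find_adapter(bases: str, adapter: str, min_len: int, min_identity: float) -> tuple[int, int] | None:
    """Best semi-global occurrence of (a suffix/prefix of) the adapter in the read.

    Returns the matched [start, end) interval in the read, or None.  Uses
    infix alignment of the adapter against the read; a hit must cover at least
    ``min_len`` read bases at ``min_identity``.
    """
    if len(adapter) < min_len or not bases:
        return None
    res = edlib.align(adapter, bases, mode="HW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = res["locations"][0]
    end += 1
    span = end - start
    if span < min_len:
        return None
    identity = 1.0 - res["editDistance"] / max(span, len(adapter))
    if identity < min_identity:
        return None
    return start, end


def _slice(read: Read, start: int, end: int) -> Read:
    return Read(
        id=read.id,
        bases=read.bases[start:end],
        quals=read.quals[start:end] if read.quals is not None else None,
        genotype=read.genotype,
        trimmed=True,
    )


def match_barcode(bases: str, barcodes: dict[str, str]) -> str | None:
    """Exact match of the first 6 bases against the barcode map."""
    prefix = bases[:6]
    for genotype, bc in barcodes.items():
        if prefix == bc:
            return genotype
    return None


def trim_read(read: Read, params: TrimParams) -> Read | Rejection:
    """Clean one read; returns the trimmed Read or a typed Rejection.

    Stage order: barcode strip, adapter removal, Mott quality trim (skipped
    without qualities), fixed terminal trim, ambiguity and length gates.
    """
    r = read
    # (1) barcode
    if params.barcodes:
        genotype = match_barcode(r.bases, params.barcodes)
        if genotype is None:
            return Rejection(read.id, "no_barcode")
        r = _slice(r, 6, len(r.bases))
        r.genotype = genotype
    # (2) adapters, at either end
    for adapter in params.adapters:
        for probe in (adapter, _revcomp(adapter)):
            hit = _find_adapter(r.bases, probe, params.adapter_min_len, params.adapter_min_identity)
            if hit is None:
                continue
            start, end = hit
            mid = len(r.bases) / 2
            if (start + end) / 2 <= mid:
                r = _slice(r, end, len(r.bases))  # 5' adapter: drop through its end
            else:
                r = _slice(r, 0, start)  # 3' adapter: drop from its start
    # (3) quality trim
    if r.quals is not None and len(r.bases) > 0:
        s, e = mott_trim_interval(r.quals, params.quality_limit)
        r = _slice(r, s, e)
    # (4) fixed terminal trim
    end = len(r.bases) - params.tail_trim
    r = _slice(r, params.head_trim, max(end, params.head_trim))
    if len(r.bases) == 0:
        return Rejection(read.id, "empty_after_trim")
    # (5) gates
    if r.bases.count("N") > params.max_ambiguous:
        return Rejection(read.id, "too_many_ambiguous")
    if len(r.bases) < params.min_len:
        return Rejection(read.id, "too_short")
    if len(r.bases) > params.max_len:
        return Rejection(read.id, "too_long")
    return r


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def demultiplex(
    reads: Iterable[Read], barcodes: dict[str, str]
) -> tuple[dict[str, list[Read]], list[Rejection]]:
    """Assign reads to genotypes by exact 6-nt barcode match, stripping the barcode."""
    bcs = list(barcodes.values())
    if len(set(bcs)) != len(bcs):
        raise ValueError("duplicate barcode strings")
    assigned: dict[str, list[Read]] = {g: [] for g in barcodes}
    rejected: list[Rejection] = []
    for r in reads:
        genotype = match_barcode(r.bases, barcodes)
        if genotype is None:
            rejected.append(Rejection(r.id, "no_barcode"))
        else:
            rr = _slice(r, 6, len(r.bases))
            rr.genotype = genotype
            assigned[genotype].append(rr)
    return assigned, rejected


def preprocess_report(n_input: int, kept: int, rejected_by_reason: dict[str, int]) -> dict:
    """Summary of a cleaning run; percentages are of the input, 1 decimal."""
    n_rejected = sum(rejected_by_reason.values())
    if kept + n_rejected != n_input:
        raise ValueError("kept + rejected must equal input")
    pct = round(n_rejected / n_input * 100, 1) if n_input else 0.0
    return {
        "input_reads": n_input,
        "kept_reads": kept,
        "rejected_reads": n_rejected,
        "rejected_pct": pct,
        "rejected_by_reason": dict(rejected_by_reason),
    }


def preprocess_reads(
    reads: Iterable[Read], params: TrimParams
) -> tuple[list[Read], list[Rejection], dict]:
    """Trim a stream of reads, returning kept reads, rejections and the report."""
    kept: list[Read] = []
    rejected: list[Rejection] = []
    n = 0
    for r in reads:
        n += 1
        out = trim_read(r, params)
        if isinstance(out, Rejection):
            rejected.append(out)
        else:
            kept.append(out)
    by_reason: dict[str, int] = {}
    for rej in rejected:
        by_reason[rej.reason] = by_reason.get(rej.reason, 0) + 1
    return kept, rejected, preprocess_report(n, len(kept), by_reason)
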