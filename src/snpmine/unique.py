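"""Marker-uniqueness screen: seed-and-extend nucleotide search with E-values.

Each candidate marker's 101-bp flank is searched against every contig of the
same assembly.  A marker whose flank matches anything other than its own source
contig at E <= 1e-20 is discarded: such a marker would cross-hybridise with a
paralogous locus (or a redundant split-allele contig) and fail in genotyping.

The search is classic seed-and-extend: exact 11-mer seeds over both strands,
gapped Smith-Waterman extension in a band around each seeded diagonal, and
Karlin-Altschul statistics (bit score S' = (lambda*S - ln K)/ln 2,
E = m*n*2^-S') with ungapped DNA constants lambda = 1.28, K = 0.46.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from snpmine.seqio import MarkerRecord

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class ScoringParams:
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5  # score of the first gapped position
    gap_extend: int = -2  # score of each further gapped position
    lambda_: float = 1.28
    k: float = 0.46

    def bit_score(self, raw: float) -> float:
        return (self.lambda_ * raw - math.log(self.k)) / math.log(2.0)

    def evalue(self, raw: float, query_len: int, db_len: int) -> float:
        return query_len * db_len * 2.0 ** (-self.bit_score(raw))


@dataclass
class SearchHit:
    query_id: str
    contig_id: str
    query_start: int  # 1-based inclusive
    query_end: int
    contig_start: int  # 1-based inclusive, forward contig coordinates
    contig_end: int
    strand: str  # "+" | "-"
    identity: float
    score: int
    bit_score: float
    e_value: float


@dataclass
class SeedIndex:
    """Exact k-mer positions over both strands of a contig set."""

    word_size: int
    contigs: dict[str, str]
    total_length: int
    # word -> list of (contig_id, strand, 0-based position in the stranded sequence)
    table: dict[str, list[tuple[str, str, int]]] = field(default_factory=dict)


def build_index(contigs: dict[str, str] | Sequence[tuple[str, str]], word_size: int = 11) -> SeedIndex:
    """Index every ``word_size``-mer of both strands of the contigs."""
    if word_size < 4:
        raise ValueError("word_size must be >= 4")
    if not isinstance(contigs, dict):
        contigs = dict(contigs)
    if not contigs:
        raise ValueError("contigs must be non-empty")
    index = SeedIndex(
        word_size=word_size,
        contigs={k: v.upper() for k, v in contigs.items()},
        total_length=sum(len(v) for v in contigs.values()),
    )
    for cid, seq in index.contigs.items():
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for i in range(len(s) - word_size + 1):
                w = s[i : i + word_size]
                if "N" in w:
                    continue
                index.table.setdefault(w, []).append((cid, strand, i))
    return index


def _encode(s: str) -> np.ndarray:
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        out[arr == b] = i
    return out


try:  # numba accelerates the DP fill; the fallback is identical pure Python
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=True)
def _sw_fill(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover - compiled
    nq, nt = len(q), len(t)
    NEG = -(10**6)
    H = np.zeros((nq + 1, nt + 1), dtype=np.int32)
    E = np.full((nq + 1, nt + 1), NEG, dtype=np.int32)
    F = np.full((nq + 1, nt + 1), NEG, dtype=np.int32)
    best_score, best_i, best_j = 0, 0, 0
    for i in range(1, nq + 1):
        qi = q[i - 1]
        for j in range(1, nt + 1):
            sub = match if (qi == t[j - 1] and qi != 4) else mismatch
            e = H[i, j - 1] + gap_open
            e2 = E[i, j - 1] + gap_extend
            if e2 > e:
                e = e2
            E[i, j] = e
            f = H[i - 1, j] + gap_open
            f2 = F[i - 1, j] + gap_extend
            if f2 > f:
                f = f2
            F[i, j] = f
            h = H[i - 1, j - 1] + sub
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best_score:
                best_score, best_i, best_j = h, i, j
    return H, E, F, best_score, best_i, best_j


def banded_local_align(
    query: str, target: str, sp: ScoringParams
) -> tuple[int, int, int, int, int, float]:
    """Affine-gap Smith-Waterman of query vs target (full matrix, small inputs).

    Returns (score, qstart, qend, tstart, tend, identity) with 0-based
    half-open intervals; identity is matches / alignment columns.
    """
    q = _encode(query)
    t = _encode(target)
    H, E, F, score, bi, bj = _sw_fill(
        q, t, sp.match, sp.mismatch, sp.gap_open, sp.gap_extend
    )
    if score <= 0:
        return 0, 0, 0, 0, 0, 0.0
    # traceback
    i, j = bi, bj
    matches = 0
    cols = 0
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] <= 0:
                break
            diag = H[i - 1, j - 1] + (sp.match if q[i - 1] == t[j - 1] and q[i - 1] != 4 else sp.mismatch)
            if H[i, j] == diag:
                matches += int(q[i - 1] == t[j - 1] and q[i - 1] != 4)
                cols += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            elif H[i, j] == F[i, j]:
                state = "F"
            else:  # pragma: no cover - defensive
                break
        elif state == "E":
            cols += 1
            j -= 1
            if E[i, j + 1] == H[i, j] + sp.gap_open:
                state = "H"
        else:  # F
            cols += 1
            i -= 1
            if F[i + 1, j] == H[i, j] + sp.gap_open:
                state = "H"
    identity = matches / cols if cols else 0.0
    return score, i, bi, j, bj, identity


def search(
    query: str,
    index: SeedIndex,
    query_id: str = "query",
    params: ScoringParams | None = None,
    max_evalue: float | None = None,
    band_margin: int = 25,
) -> list[SearchHit]:
    """Seed-and-extend search of a query against the indexed contigs.

    Seeds on nearby diagonals of one contig strand are merged into one
    extension window; overlapping hits on a contig keep only the best.  Hits
    are reported on forward contig coordinates with a strand flag, sorted by
    E-value ascending.
    """
    sp = params or ScoringParams()
    query = query.upper()
    w = index.word_size
    m = len(query)
    # gather seeds per (contig, strand), as (diagonal, target position)
    seeds: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    for qpos in range(m - w + 1):
        word = query[qpos : qpos + w]
        for cid, strand, tpos in index.table.get(word, ()):
            seeds.setdefault((cid, strand), []).append((tpos - qpos, qpos, tpos))
    raw_hits: list[SearchHit] = []
    for (cid, strand), lst in seeds.items():
        seq = index.contigs[cid] if strand == "+" else revcomp(index.contigs[cid])
        # cluster seeds by diagonal
        lst.sort()
        clusters: list[list[tuple[int, int, int]]] = []
        for d, qpos, tpos in lst:
            if clusters and d - clusters[-1][-1][0] <= 2 * band_margin:
                clusters[-1].append((d, qpos, tpos))
            else:
                clusters.append([(d, qpos, tpos)])
        for cluster in clusters:
            t_lo = min(tp - qp for _, qp, tp in cluster)
            t_hi = max(tp + (m - qp) for _, qp, tp in cluster)
            lo = max(0, t_lo - band_margin)
            hi = min(len(seq), t_hi + band_margin)
            window = seq[lo:hi]
            score, qs, qe, ts, te, ident = banded_local_align(query, window, sp)
            if score <= 0:
                continue
            e = sp.evalue(score, m, index.total_length)
            if max_evalue is not None and e > max_evalue:
                continue
            # map window coordinates back to forward contig coordinates
            s0, e0 = lo + ts, lo + te  # 0-based half-open on stranded seq
            if strand == "+":
                cstart, cend = s0 + 1, e0
            else:
                L = len(seq)
                cstart, cend = L - e0 + 1, L - s0
            raw_hits.append(
                SearchHit(
                    query_id=query_id,
                    contig_id=cid,
                    query_start=qs + 1,
                    query_end=qe,
                    contig_start=cstart,
                    contig_end=cend,
                    strand=strand,
                    identity=ident,
                    score=score,
                    bit_score=sp.bit_score(score),
                    e_value=e,
                )
            )
    # merge overlapping intervals per contig, keeping the best-scoring hit
    raw_hits.sort(key=lambda h: (h.e_value, h.contig_id, h.contig_start))
    merged: list[SearchHit] = []
    for h in raw_hits:
        redundant = False
        for kept in merged:
            if kept.contig_id == h.contig_id and not (
                h.contig_end < kept.contig_start or h.contig_start > kept.contig_end
            ):
                redundant = True
                break
        if not redundant:
            merged.append(h)
    return merged


def filter_unique(
    markers: Sequence[MarkerRecord],
    hits_by_marker: dict[str, list[SearchHit]],
    threshold: float = 1e-20,
) -> tuple[list[MarkerRecord], list[dict]]:
    """Retain markers whose sole hit at the threshold is their source contig.

    Discard reasons: ``no_hit`` (nothing at the threshold — pathological),
    ``multi_hit`` (more than one above-threshold hit, including tandem copies
    within the source contig), ``wrong_contig`` (single hit elsewhere).
    Idempotent and order-independent.
    """
    retained: list[MarkerRecord] = []
    ledger: list[dict] = []
    for m in markers:
        hits = [h for h in hits_by_marker.get(m.marker_id, []) if h.e_value <= threshold]
        if len(hits) == 0:
            reason = "no_hit"
        elif len(hits) > 1:
            reason = "multi_hit"
        elif hits[0].contig_id != m.contig_id:
            reason = "wrong_contig"
        else:
            reason = None
        if reason is None:
            m.status.append(("unique", "pass"))
            retained.append(m)
        else:
            m.status.append(("unique", "fail"))
            ledger.append({"marker_id": m.marker_id, "reason": reason, "n_hits": len(hits)})
    return retained, ledger


def hit_histogram(
    markers: Sequence[MarkerRecord],
    hits_by_marker: dict[str, list[SearchHit]],
    threshold: float = 1e-20,
) -> dict:
    """Distribution of above-threshold hit counts per marker, plus unique fraction."""
    bins = {str(i): 0 for i in range(1, 11)}
    bins[">10"] = 0
    bins["0"] = 0
    n_unique = 0
    for m in markers:
        n = sum(1 for h in hits_by_marker.get(m.marker_id, []) if h.e_value <= threshold)
        if n == 1:
            n_unique += 1
        key = str(n) if 0 <= n <= 10 else ">10"
        bins[key] += 1
    total = len(markers)
    return {
        "bins": bins,
        "n_markers": total,
        "unique_fraction": n_unique / total if total else 0.0,
        "unique_pct": round(n_unique / total * 100, 1) if total else 0.0,
    }


def screen_markers(
    markers: Sequence[MarkerRecord],
    contigs: dict[str, str],
    threshold: float = 1e-20,
    word_size: int = 11,
    params: ScoringParams | None = None,
) -> tuple[list[MarkerRecord], list[dict], dict]:
    """Convenience wrapper: index, search every marker flank, filter, histogram."""
    index = build_index(contigs, word_size=word_size)
    hits_by_marker = {
        m.marker_id: search(m.flank_seq, index, query_id=m.marker_id, params=params)
        for m in markers
    }
    retained, ledger = filter_unique(markers, hits_by_marker, threshold)
    histogram = hit_histogram(markers, hits_by_marker, threshold)
    return retained, ledger, histogram
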