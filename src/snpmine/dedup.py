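"""Clonal (duplicate) read removal.

PCR and emulsion-PCR duplicates inflate allele counts and turn single
polymerase errors into apparent polymorphisms, so they must be removed before
SNP calling.  Because the libraries are built by random priming (not shearing),
true duplicates start at the same template position: they share their first
bases and are near-identical over their common length.  We cluster greedily,
CD-HIT style: reads sorted by length descending, bucketed by their first
``prefix_len`` bases; a read joins the first cluster whose representative it
matches at >= ``min_identity`` global identity over the shorter read's length,
anchored at the shared prefix.  Only the longest member (the representative)
is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib

from snpmine.seqio import Read

logger = logging.getLogger(__name__)


@dataclass
class CloneCluster:
    representative: Read
    members: list[Read] = field(default_factory=list)  # excludes the representative
    identities: list[float] = field(default_factory=list)


def prefix_anchored_identity(shorter: str, longer: str) -> float:
    """Identity of ``shorter`` against a start-anchored alignment into ``longer``.

    Semi-global (prefix) alignment: the shorter read must align from the start
    of the longer one; unaligned longer-read tail is free.  Identity is
    1 - edits / len(shorter).
    """
    if not shorter:
        return 0.0
    res = edlib.align(shorter, longer, mode="SHW")
    return 1.0 - res["editDistance"] / len(shorter)


def cluster_clones(
    reads: Sequence[Read], prefix_len: int = 6, min_identity: float = 0.98
) -> list[CloneCluster]:
    """Greedy duplicate clustering; deterministic under input permutation.

    Reads shorter than ``prefix_len`` each found a singleton cluster.
    """
    ordered = sorted(reads, key=lambda r: (-len(r.bases), r.id))
    buckets: dict[str, list[CloneCluster]] = {}
    clusters: list[CloneCluster] = []
    for r in ordered:
        if len(r.bases) < prefix_len:
            logger.info("read %s shorter than prefix length; kept as singleton", r.id)
            c = CloneCluster(representative=r)
            clusters.append(c)
            continue
        key = r.bases[:prefix_len]
        bucket = buckets.setdefault(key, [])
        placed = False
        for c in bucket:
            rep = c.representative
            shorter, longer = (r.bases, rep.bases) if len(r.bases) <= len(rep.bases) else (rep.bases, r.bases)
            ident = prefix_anchored_identity(shorter, longer)
            if ident >= min_identity:
                c.members.append(r)
                c.identities.append(ident)
                placed = True
                break
        if not placed:
            c = CloneCluster(representative=r)
            bucket.append(c)
            clusters.append(c)
    return clusters


def deduplicate(
    reads: Sequence[Read], prefix_len: int = 6, min_identity: float = 0.98
) -> tuple[list[Read], dict]:
    """Remove clonal reads, keeping each cluster's longest member.

    Returns kept reads (in cluster-founding order) and a removal report with
    one row per removed read naming its representative.
    """
    clusters = cluster_clones(reads, prefix_len=prefix_len, min_identity=min_identity)
    kept = []
    removals = []
    for c in clusters:
        rep = c.representative
        rep.clonal_representative = bool(c.members)
        kept.append(rep)
        for m, ident in zip(c.members, c.identities):
            removals.append({"read_id": m.id, "representative_id": rep.id, "identity": ident})
    n_input = len(reads)
    n_removed = len(removals)
    report = {
        "input_reads": n_input,
        "kept_reads": len(kept),
        "removed_reads": n_removed,
        "removed_pct": round(n_removed / n_input * 100, 1) if n_input else 0.0,
        "removals": removals,
        "rule": f"prefix_len={prefix_len}, global identity >= {min_identity} over the shorter read",
    }
    return kept, report
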