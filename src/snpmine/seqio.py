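"""Readers and writers for reads, contig alignments and marker records.

Coordinates reported to the user are 1-based inclusive on the ungapped contig
consensus; padded (gapped) columns exist only inside :class:`ContigAlignment`.
Pads are represented by ``*`` as in ACE files.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam
from Bio import SeqIO
from Bio.Sequencing import Ace

logger = logging.getLogger(__name__)

PAD = "*"

#: IUPAC ambiguity code for an unordered pair of bases.
IUPAC = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}


class FormatError(ValueError):
    """A record violates the format contract (e.g. qual/sequence length mismatch)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Read:
    """A sequenced read with optional per-base error probabilities.

    ``quals`` holds error probabilities in [0, 1] (``p = 10**(-Q/10)``), not
    Phred scores; ``None`` for FASTA-only input.
    """

    id: str
    bases: str
    quals: list[float] | None = None
    genotype: str = ""
    trimmed: bool = False
    clonal_representative: bool = False

    def __post_init__(self) -> None:
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise FormatError(
                f"read {self.id!r}: {len(self.quals)} qualities for {len(self.bases)} bases"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class AlignedMember:
    """One read laid out in the padded coordinate system of its contig."""

    read_id: str
    genotype: str
    aligned: str  # padded string, PAD for gaps
    offset: int  # 0-based start column in the padded consensus

    @property
    def end(self) -> int:
        """One past the last padded column covered."""
        return self.offset + len(self.aligned)


@dataclass
class ContigAlignment:
    """A contig consensus plus the padded layout of its member reads."""

    contig_id: str
    consensus: str  # padded; PAD allowed
    members: list[AlignedMember] = field(default_factory=list)

    def __post_init__(self) -> None:
        for m in self.members:
            if m.offset < 0 or m.end > len(self.consensus):
                raise ValueError(
                    f"member {m.read_id!r} exceeds consensus bounds of {self.contig_id!r}"
                )

    @property
    def ungapped_consensus(self) -> str:
        return self.consensus.replace(PAD, "")

    @property
    def ungapped_length(self) -> int:
        return len(self.consensus) - self.consensus.count(PAD)

    def padded_to_ungapped(self) -> list[int]:
        """For each padded column, the 1-based ungapped position (0 at pad columns)."""
        out, pos = [], 0
        for c in self.consensus:
            if c == PAD:
                out.append(0)
            else:
                pos += 1
                out.append(pos)
        return out

    def column(self, padded_pos: int) -> list[tuple[str, str, str]]:
        """Bases covering one padded column as (read_id, genotype, base-or-PAD)."""
        out = []
        for m in self.members:
            if m.offset <= padded_pos < m.end:
                out.append((m.read_id, m.genotype, m.aligned[padded_pos - m.offset]))
        return out


@dataclass
class MarkerRecord:
    """A candidate SNP marker: the variant plus its 101-bp flank and filter ledger.

    ``position`` is 1-based on the ungapped consensus and corresponds to base 51
    (1-based) of ``flank_seq``.
    """

    marker_id: str
    contig_id: str
    position: int
    alleles: tuple[str, str]
    snp_class: str  # "intra" | "inter"
    d_value: float
    haplotype_count: int
    flank_seq: str
    status: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.flank_seq) != 101:
            raise ValueError(f"marker {self.marker_id!r}: flank is {len(self.flank_seq)} bp, not 101")
        if self.d_value < 0:
            raise ValueError("d_value must be non-negative")

    @property
    def passed(self) -> bool:
        return all(v == "pass" for _, v in self.status)


# ---------------------------------------------------------------------------
# read ingestion
# ---------------------------------------------------------------------------


def phred_to_error(q: float) -> float:
    return 10.0 ** (-q / 10.0)


def error_to_phred(p: float) -> int:
    import math

    p = min(max(p, 1e-9), 1.0)
    return int(round(-10.0 * math.log10(p)))


def read_sequences(path: str | Path, format: str = "fastq") -> Iterator[Read]:
    """Stream reads from FASTA, FASTQ (Sanger Phred+33) or FASTA plus .qual.

    FASTA-only input yields reads with ``quals=None``.  ``fasta+qual`` expects a
    sibling ``<path>.qual`` (or the given path with suffix replaced by .qual).
    """
    path = Path(path)
    if format == "fastq":
        it = SeqIO.parse(str(path), "fastq")
        i = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                break
            except Exception as exc:
                raise FormatError(f"malformed FASTQ record #{i + 1} in {path}: {exc}") from exc
            i += 1
            quals = [phred_to_error(q) for q in rec.letter_annotations["phred_quality"]]
            yield Read(id=rec.id, bases=str(rec.seq).upper(), quals=quals)
    elif format == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            yield Read(id=rec.id, bases=str(rec.seq).upper(), quals=None)
    elif format == "fasta+qual":
        qual_path = path.with_suffix(".qual")
        quals_by_id = {
            rec.id: rec.letter_annotations["phred_quality"]
            for rec in SeqIO.parse(str(qual_path), "qual")
        }
        for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
            q = quals_by_id.get(rec.id)
            if q is None:
                raise FormatError(f"record #{i + 1} ({rec.id!r}): no entry in {qual_path}")
            if len(q) != len(rec.seq):
                raise FormatError(
                    f"record #{i + 1} ({rec.id!r}): {len(q)} qualities for {len(rec.seq)} bases"
                )
            yield Read(id=rec.id, bases=str(rec.seq).upper(), quals=[phred_to_error(x) for x in q])
    else:
        raise ValueError(f"unknown format {format!r}")


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            quals = r.quals if r.quals is not None else [phred_to_error(30)] * len(r)
            qline = "".join(chr(error_to_phred(p) + 33) for p in quals)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{qline}\n")


def write_fasta(seqs: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# assembly ingestion (ACE / SAM)
# ---------------------------------------------------------------------------

DEFAULT_GENOTYPE_PATTERN = r"^([^_]+)_"


def genotype_from_name(
    read_id: str, pattern: str = DEFAULT_GENOTYPE_PATTERN, on_unknown: str = "unknown"
) -> str:
    m = re.match(pattern, read_id)
    if m:
        return m.group(1)
    if on_unknown == "error":
        raise ValueError(f"cannot recover genotype label from read name {read_id!r}")
    return "unknown"


def _read_ace(path: Path, genotype_pattern: str, on_unknown: str) -> Iterator[ContigAlignment]:
    for contig in Ace.parse(str(path)):
        offsets = {af.name: af.padded_start for af in contig.af}
        members = []
        for rd in contig.reads:
            name = rd.rd.name
            start = offsets[name] - 1  # AF padded_start is 1-based
            aligned = rd.rd.sequence.upper()
            # QA clipping: keep the aligned (non-clipped) segment only
            if rd.qa is not None and rd.qa.align_clipping_start > 0:
                a0 = rd.qa.align_clipping_start - 1
                a1 = rd.qa.align_clipping_end
                aligned = aligned[a0:a1]
                start += a0
            members.append(
                AlignedMember(
                    read_id=name,
                    genotype=genotype_from_name(name, genotype_pattern, on_unknown),
                    aligned=aligned,
                    offset=start,
                )
            )
        yield ContigAlignment(
            contig_id=contig.name, consensus=contig.sequence.upper(), members=members
        )


#: parsed alignment row: (read_id, genotype, events); an event is
#: ("M"|"D", ref_pos, length, seq) or ("I", ref_pos_before, length, seq)
AlignmentRow = tuple[str, str, list[tuple[str, int, int, str]]]


def build_padded_alignment(
    contig_id: str, consensus_ungapped: str, rows: Sequence[AlignmentRow]
) -> ContigAlignment:
    """Lay out per-read CIGAR-style alignments as one padded multiple alignment.

    Insertions relative to the consensus open shared pad columns sized to the
    largest insertion at that position.
    """
    # maximal insertion length after each ungapped position (0-based, -1 = before start)
    ins_after: dict[int, int] = {}
    parsed = []
    for read_id, genotype, events in rows:
        for op, refpos, ln, _seq in events:
            if op == "I":
                ins_after[refpos] = max(ins_after.get(refpos, 0), ln)
        parsed.append((read_id, genotype, events))

    # padded column index of each ungapped consensus position
    col_of: list[int] = []
    consensus_chars: list[str] = []
    if ins_after.get(-1):
        consensus_chars.extend(PAD * ins_after[-1])
    for i, base in enumerate(consensus_ungapped):
        col_of.append(len(consensus_chars))
        consensus_chars.append(base)
        if ins_after.get(i):
            consensus_chars.extend(PAD * ins_after[i])
    consensus = "".join(consensus_chars)

    def col(pos: int) -> int:
        return col_of[pos]

    members = []
    for name, genotype, events in parsed:
        if not events:
            continue
        first_ref = next(e[1] for e in events if e[0] in ("M", "D"))
        start_col = col(first_ref)
        buf: list[str] = []
        cur_col = start_col
        for op, refpos, ln, seq in events:
            if op == "M":
                for k in range(ln):
                    target = col(refpos + k)
                    buf.extend(PAD * (target - cur_col))
                    buf.append(seq[k])
                    cur_col = target + 1
            elif op == "D":
                for k in range(ln):
                    target = col(refpos + k)
                    buf.extend(PAD * (target - cur_col))
                    buf.append(PAD)
                    cur_col = target + 1
            elif op == "I":
                # occupies pad columns right after refpos
                buf.extend(seq)
                cur_col += ln
        members.append(
            AlignedMember(
                read_id=name,
                genotype=genotype,
                aligned="".join(buf),
                offset=start_col,
            )
        )
    return ContigAlignment(contig_id=contig_id, consensus=consensus, members=members)


def _build_from_sam(
    contig_id: str,
    consensus_ungapped: str,
    alns: "list[pysam.AlignedSegment]",
    genotype_pattern: str,
    on_unknown: str,
) -> ContigAlignment:
    rows: list[AlignmentRow] = []
    for aln in alns:
        ref = aln.reference_start  # 0-based
        q = aln.query_sequence.upper()
        qi = 0
        events: list[tuple[str, int, int, str]] = []
        for op, ln in aln.cigartuples:
            if op in (4, 5):  # soft/hard clip: excluded from member columns
                if op == 4:
                    qi += ln
            elif op in (0, 7, 8):  # M/=/X
                events.append(("M", ref, ln, q[qi : qi + ln]))
                ref += ln
                qi += ln
            elif op == 1:
                events.append(("I", ref - 1, ln, q[qi : qi + ln]))
                qi += ln
            elif op == 2:
                events.append(("D", ref, ln, ""))
                ref += ln
            else:
                raise ValueError(f"unsupported CIGAR op {op} in read {aln.query_name!r}")
        rows.append(
            (aln.query_name, genotype_from_name(aln.query_name, genotype_pattern, on_unknown), events)
        )
    return build_padded_alignment(contig_id, consensus_ungapped, rows)


def read_assembly(
    consensus_path: str | Path,
    alignment_path: str | Path,
    format: str | None = None,
    genotype_pattern: str = DEFAULT_GENOTYPE_PATTERN,
    on_unknown_genotype: str = "unknown",
    allow_empty: bool = False,
) -> Iterator[ContigAlignment]:
    """Import an external assembly: consensus FASTA plus ACE or SAM alignments.

    ``format`` is inferred from the alignment file suffix when omitted.  Contigs
    present in the consensus but absent from the alignment are skipped with a
    warning unless ``allow_empty`` is set, in which case they are emitted with
    zero members.
    """
    consensus_path = Path(consensus_path)
    alignment_path = Path(alignment_path)
    if format is None:
        format = "ace" if alignment_path.suffix.lower() == ".ace" else "sam"
    consensi = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(consensus_path), "fasta")
    }
    seen = set()
    if format == "ace":
        for aln in _read_ace(alignment_path, genotype_pattern, on_unknown_genotype):
            if aln.contig_id not in consensi:
                raise ValueError(f"alignment references unknown contig {aln.contig_id!r}")
            seen.add(aln.contig_id)
            yield aln
    elif format == "sam":
        with pysam.AlignmentFile(str(alignment_path), "r", check_sq=False) as sam:
            per_contig: dict[str, list[pysam.AlignedSegment]] = {}
            for aln in sam:
                if aln.is_unmapped:
                    continue
                name = aln.reference_name
                if name not in consensi:
                    raise ValueError(f"read {aln.query_name!r} mapped to unknown contig {name!r}")
                per_contig.setdefault(name, []).append(aln)
        for name, alns in per_contig.items():
            seen.add(name)
            yield _build_from_sam(name, consensi[name], alns, genotype_pattern, on_unknown_genotype)
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    for name in consensi:
        if name not in seen:
            if allow_empty:
                yield ContigAlignment(contig_id=name, consensus=consensi[name], members=[])
            else:
                logger.warning("contig %s has no aligned reads; skipped", name)


# ---------------------------------------------------------------------------
# assembly export (used by the synthetic-data generator and tests)
# ---------------------------------------------------------------------------


def write_ace(alignments: Sequence[ContigAlignment], path: str | Path) -> None:
    """Write a minimal phrap/CAP3-dialect ACE file (CO/BQ/AF/BS/RD/QA records)."""
    alignments = list(alignments)
    n_reads = sum(len(a.members) for a in alignments)
    with open(path, "w") as fh:
        fh.write(f"AS {len(alignments)} {n_reads}\n\n")
        for a in alignments:
            fh.write(
                f"CO {a.contig_id} {len(a.consensus)} {len(a.members)} 1 U\n"
            )
            for i in range(0, len(a.consensus), 50):
                fh.write(a.consensus[i : i + 50] + "\n")
            fh.write("\nBQ\n")
            quals = " ".join(["40"] * a.ungapped_length)
            fh.write(quals + "\n\n")
            for m in a.members:
                fh.write(f"AF {m.read_id} U {m.offset + 1}\n")
            if alignments and a.members:
                m0 = a.members[0]
                fh.write(f"BS {m0.offset + 1} {m0.end} {m0.read_id}\n")
            fh.write("\n")
            for m in a.members:
                fh.write(f"RD {m.read_id} {len(m.aligned)} 0 0\n")
                for i in range(0, len(m.aligned), 50):
                    fh.write(m.aligned[i : i + 50] + "\n")
                fh.write(f"\nQA 1 {len(m.aligned)} 1 {len(m.aligned)}\n")
                fh.write("DS CHROMAT_FILE: x PHD_FILE: x TIME: x\n\n")


def _cigar_from_padded(consensus: str, member: AlignedMember) -> tuple[int, list[tuple[int, int]], str]:
    """CIGAR of a padded member against the ungapped consensus.

    Returns (0-based ungapped ref start, cigartuples, gapless read sequence).
    """
    ref_start = len(consensus[: member.offset].replace(PAD, ""))
    ops: list[tuple[int, int]] = []
    seq_chars: list[str] = []

    def push(op: int, ln: int = 1) -> None:
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + ln)
        else:
            ops.append((op, ln))

    for i, rbase in enumerate(member.aligned):
        cbase = consensus[member.offset + i]
        if rbase == PAD and cbase == PAD:
            continue
        if rbase == PAD:
            push(2)  # D
        elif cbase == PAD:
            push(1)  # I
            seq_chars.append(rbase)
        else:
            push(0)  # M
            seq_chars.append(rbase)
    # leading/trailing deletions are meaningless in SAM
    while ops and ops[0][0] == 2:
        ref_start += ops[0][1]
        ops.pop(0)
    while ops and ops[-1][0] == 2:
        ops.pop()
    return ref_start, ops, "".join(seq_chars)


def write_sam(alignments: Sequence[ContigAlignment], path: str | Path) -> None:
    """Write a plain-text SAM file of member reads against ungapped consensi."""
    alignments = list(alignments)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": a.contig_id, "LN": a.ungapped_length} for a in alignments
        ],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for a in alignments:
            for m in a.members:
                ref_start, cig, seq = _cigar_from_padded(a.consensus, m)
                seg = pysam.AlignedSegment(out.header)
                seg.query_name = m.read_id
                seg.query_sequence = seq
                seg.reference_name = a.contig_id
                seg.reference_start = ref_start
                seg.cigartuples = cig
                seg.mapping_quality = 60
                seg.flag = 0
                out.write(seg)


# ---------------------------------------------------------------------------
# marker output
# ---------------------------------------------------------------------------

MARKER_TSV_COLUMNS = [
    "marker_id",
    "contig_id",
    "position",
    "allele1",
    "allele2",
    "snp_class",
    "d_value",
    "haplotype_count",
    "flank_seq",
    "filters",
]


def iupac_code(a: str, b: str) -> str:
    try:
        return IUPAC[frozenset((a.upper(), b.upper()))]
    except KeyError:
        return "N"


def write_markers(
    markers: Sequence[MarkerRecord], tsv_path: str | Path, fasta_path: str | Path
) -> None:
    """Write the marker table (TSV) and the 101-bp flank FASTA.

    In the FASTA the variant base (position 51) is encoded as its IUPAC
    ambiguity code.  Output is byte-stable for identical input.
    """
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(MARKER_TSV_COLUMNS) + "\n")
        for m in markers:
            filters = ";".join(f"{name}={verdict}" for name, verdict in m.status)
            fh.write(
                "\t".join(
                    [
                        m.marker_id,
                        m.contig_id,
                        str(m.position),
                        m.alleles[0],
                        m.alleles[1],
                        m.snp_class,
                        repr(m.d_value),
                        str(m.haplotype_count),
                        m.flank_seq,
                        filters,
                    ]
                )
                + "\n"
            )
    with open(fasta_path, "w") as fh:
        for m in markers:
            flank = m.flank_seq[:50] + iupac_code(*m.alleles) + m.flank_seq[51:]
            fh.write(f">{m.marker_id} {m.contig_id}:{m.position} {m.alleles[0]}/{m.alleles[1]}\n")
            fh.write(flank + "\n")


def read_markers(tsv_path: str | Path) -> list[MarkerRecord]:
    """Re-read a marker TSV written by :func:`write_markers` (lossless)."""
    out = []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != MARKER_TSV_COLUMNS:
            raise FormatError(f"unexpected marker TSV header in {tsv_path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            status = []
            if f[9]:
                for item in f[9].split(";"):
                    name, verdict = item.split("=")
                    status.append((name, verdict))
            out.append(
                MarkerRecord(
                    marker_id=f[0],
                    contig_id=f[1],
                    position=int(f[2]),
                    alleles=(f[3], f[4]),
                    snp_class=f[5],
                    d_value=float(f[6]),
                    haplotype_count=int(f[7]),
                    flank_seq=f[8],
                    status=status,
                )
            )
    return out
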