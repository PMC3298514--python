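"""Format readers/writers: FASTQ/FASTA ingestion, ACE/SAM import, marker output."""

import math

import pytest

from snpmine import seqio
from snpmine.seqio import (
    ContigAlignment,
    FormatError,
    MarkerRecord,
    Read,
    genotype_from_name,
    read_markers,
    read_sequences,
    write_markers,
)


def write(path, text):
    path.write_text(text)
    return str(path)


class TestReadSequences:
    def test_fastq_quality_converted_to_error_probability(self, tmp_path):
        p = write(tmp_path / "r.fastq", "@r1\nACGT\n+\n5555\n@r2\nGGCC\n+\n5555\n")
        reads = list(read_sequences(p, "fastq"))
        assert [r.id for r in reads] == ["r1", "r2"]
        for r in reads:
            assert all(math.isclose(q, 0.01) for q in r.quals)  # Q20

    def test_empty_file_yields_empty_stream(self, tmp_path):
        p = write(tmp_path / "e.fastq", "")
        assert list(read_sequences(p, "fastq")) == []

    def test_truncated_quality_line_names_the_record(self, tmp_path):
        p = write(tmp_path / "bad.fastq", "@r1\nACGT\n+\n55\n")
        with pytest.raises(FormatError, match="#1"):
            list(read_sequences(p, "fastq"))

    def test_fasta_reads_have_no_qualities(self, tmp_path):
        p = write(tmp_path / "r.fasta", ">r1\nACGTACGT\n")
        (r,) = read_sequences(p, "fasta")
        assert r.quals is None and r.bases == "ACGTACGT"

    def test_fasta_plus_qual_merges_scores(self, tmp_path):
        write(tmp_path / "r.fasta", ">r1\nACGT\n")
        write(tmp_path / "r.qual", ">r1\n20 20 30 30\n")
        (r,) = read_sequences(tmp_path / "r.fasta", "fasta+qual")
        assert math.isclose(r.quals[0], 0.01) and math.isclose(r.quals[2], 0.001)

    def test_mismatched_qual_length_raises(self, tmp_path):
        write(tmp_path / "r.fasta", ">r1\nACGT\n")
        write(tmp_path / "r.qual", ">r1\n20 20\n")
        with pytest.raises(FormatError):
            list(read_sequences(tmp_path / "r.fasta", "fasta+qual"))


class TestGenotypeRecovery:
    def test_default_pattern_takes_leading_token(self):
        assert genotype_from_name("g3_000123") == "g3"

    def test_unmatchable_name_configurable(self):
        assert genotype_from_name("noseparator") == "unknown"
        with pytest.raises(ValueError):
            genotype_from_name("noseparator", on_unknown="error")


class TestAssemblyImport:
    def test_ace_and_sam_readers_agree(self, tmp_path, small_sim):
        contigs = small_sim["contigs"][:3]
        fa, ace, sam = (str(tmp_path / n) for n in ("c.fasta", "c.ace", "c.sam"))
        seqio.write_fasta(((c.contig_id, c.ungapped_consensus) for c in contigs), fa)
        seqio.write_ace(contigs, ace)
        seqio.write_sam(contigs, sam)
        from_ace = {a.contig_id: a for a in seqio.read_assembly(fa, ace)}
        from_sam = {a.contig_id: a for a in seqio.read_assembly(fa, sam)}
        assert set(from_ace) == set(from_sam) == {c.contig_id for c in contigs}
        for c in contigs:
            a, s = from_ace[c.contig_id], from_sam[c.contig_id]
            assert a.ungapped_consensus == s.ungapped_consensus == c.ungapped_consensus
            assert {m.read_id: (m.offset, m.aligned) for m in a.members} == {
                m.read_id: (m.offset, m.aligned) for m in c.members
            }
            # SAM normalizes terminal deletions; compare gapless content
            sam_content = {m.read_id: m.aligned.replace("*", "") for m in s.members}
            assert sam_content == {m.read_id: m.aligned.replace("*", "") for m in c.members}
            assert {m.read_id: m.genotype for m in a.members} == {
                m.read_id: m.genotype for m in s.members
            }

    def test_unreferenced_contig_skipped_unless_allow_empty(self, tmp_path, small_sim):
        contigs = small_sim["contigs"][:2]
        fa, ace = str(tmp_path / "c.fasta"), str(tmp_path / "c.ace")
        extra = [(c.contig_id, c.ungapped_consensus) for c in contigs] + [("lonely", "ACGT" * 30)]
        seqio.write_fasta(extra, fa)
        seqio.write_ace(contigs, ace)
        assert {a.contig_id for a in seqio.read_assembly(fa, ace)} == {
            c.contig_id for c in contigs
        }
        with_empty = {a.contig_id: a for a in seqio.read_assembly(fa, ace, allow_empty=True)}
        assert with_empty["lonely"].members == []

    def test_read_mapped_to_unknown_contig_raises(self, tmp_path, small_sim):
        contigs = small_sim["contigs"][:2]
        fa, sam = str(tmp_path / "c.fasta"), str(tmp_path / "c.sam")
        seqio.write_fasta([(contigs[0].contig_id, contigs[0].ungapped_consensus)], fa)
        seqio.write_sam(contigs, sam)
        with pytest.raises(ValueError, match="unknown contig"):
            list(seqio.read_assembly(fa, sam))

    def test_soft_clipped_bases_excluded(self, tmp_path):
        fa = write(tmp_path / "c.fasta", ">c1\n" + "ACGTACGTACGTACGTACGT" + "\n")
        sam = write(
            tmp_path / "c.sam",
            "@HD\tVN:1.6\n@SQ\tSN:c1\tLN:20\n"
            "g1_r1\t0\tc1\t5\t60\t3S8M\t*\t0\t0\tTTTACGTACGT\t*\n",
        )
        (aln,) = seqio.read_assembly(fa, sam)
        (m,) = aln.members
        assert m.aligned == "ACGTACGT"
        assert m.offset == 4


class TestMarkerIO:
    def make_marker(self, i=1, alleles=("A", "G")):
        flank = ("ACGTG" * 21)[:101]
        return MarkerRecord(
            marker_id=f"m{i}",
            contig_id="c1",
            position=100 + i,
            alleles=alleles,
            snp_class="intra",
            d_value=0.25,
            haplotype_count=4,
            flank_seq=flank,
            status=[("reliable", "pass"), ("unique", "pass")],
        )

    def test_roundtrip_is_lossless(self, tmp_path):
        markers = [self.make_marker(1), self.make_marker(2, ("C", "T"))]
        tsv, fa = str(tmp_path / "m.tsv"), str(tmp_path / "m.fasta")
        write_markers(markers, tsv, fa)
        back = read_markers(tsv)
        assert back == markers

    def test_fasta_encodes_snp_as_iupac_at_position_51(self, tmp_path):
        m = self.make_marker(1, ("A", "G"))
        tsv, fa = str(tmp_path / "m.tsv"), str(tmp_path / "m.fasta")
        write_markers([m], tsv, fa)
        lines = open(fa).read().splitlines()
        assert lines[1][50] == "R"
        assert len(lines[1]) == 101

    def test_zero_markers_writes_header_only(self, tmp_path):
        tsv, fa = str(tmp_path / "m.tsv"), str(tmp_path / "m.fasta")
        write_markers([], tsv, fa)
        assert open(tsv).read().count("\n") == 1
        assert open(fa).read() == ""

    def test_two_markers_one_contig_distinct_ids(self, tmp_path):
        tsv, fa = str(tmp_path / "m.tsv"), str(tmp_path / "m.fasta")
        write_markers([self.make_marker(1), self.make_marker(2)], tsv, fa)
        heads = [l for l in open(fa) if l.startswith(">")]
        assert len(heads) == len(set(heads)) == 2

    def test_flank_length_enforced(self):
        with pytest.raises(ValueError):
            MarkerRecord("m", "c", 60, ("A", "G"), "intra", 0.0, 2, "ACGT" * 10)


class TestContigAlignment:
    def test_member_must_fit_consensus(self):
        with pytest.raises(ValueError):
            ContigAlignment(
                "c", "ACGT", [seqio.AlignedMember("r", "g", "ACGTA", 0)]
            )

    def test_ungapped_length_drops_pads(self):
        aln = ContigAlignment("c", "AC*GT", [])
        assert aln.ungapped_length == 4
        assert aln.padded_to_ungapped() == [1, 2, 0, 3, 4]
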