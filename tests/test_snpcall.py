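"""SNP detection, haplotype reconstruction, D-value, reliability filters."""

import math

import pytest

from snpmine.seqio import AlignedMember, ContigAlignment
from snpmine.snpcall import (
    Haplotype,
    VariantColumn,
    classify_snp,
    d_value,
    detect_potential_snps,
    extract_marker,
    filter_reliable,
    flag_chimera,
    haplotype_ceiling,
    reconstruct_haplotypes,
    ContigSnpReport,
)


def make_alignment(consensus, rows):
    """rows: (read_id, genotype, aligned, offset)"""
    return ContigAlignment(
        "c1", consensus, [AlignedMember(*r) for r in rows]
    )


def uniform_alignment(base_seq, variants, n_each=3, genotypes=("g1",)):
    """Full-length reads; ``variants`` maps position(0-based) -> alt base for
    half the reads."""
    rows = []
    i = 0
    alt_seq = list(base_seq)
    for p, alt in variants.items():
        alt_seq[p] = alt
    alt_seq = "".join(alt_seq)
    for g in genotypes:
        for k in range(n_each):
            rows.append((f"{g}_a{i}", g, base_seq, 0))
            rows.append((f"{g}_b{i}", g, alt_seq, 0))
            i += 1
    return make_alignment(base_seq, rows)


class TestDetect:
    def test_two_reads_per_allele_is_a_potential_snp(self):
        seq = "ACGTACGTAC"
        aln = make_alignment(
            seq,
            [("r1", "g", seq, 0), ("r2", "g", seq, 0), ("r3", "g", seq, 0)]
            + [("r4", "g", seq[:4] + "G" + seq[5:], 0), ("r5", "g", seq[:4] + "G" + seq[5:], 0)],
        )
        cols = detect_potential_snps(aln)
        assert [(c.position, c.is_indel_column) for c in cols] == [(5, False)]

    def test_single_read_allele_is_not_a_snp(self):
        seq = "ACGTACGTAC"
        aln = make_alignment(
            seq,
            [("r%d" % i, "g", seq, 0) for i in range(5)]
            + [("alt", "g", seq[:4] + "G" + seq[5:], 0)],
        )
        assert detect_potential_snps(aln) == []

    def test_monomorphic_contig_gives_empty_list(self):
        seq = "ACGTACGTAC"
        aln = make_alignment(seq, [("r%d" % i, "g", seq, 0) for i in range(6)])
        assert detect_potential_snps(aln) == []

    def test_pad_column_recorded_as_indel_not_snp(self):
        seq = "ACGT*CGTAC"  # pad in consensus
        with_ins = "ACGTACGTAC"
        without = "ACGT*CGTAC"
        aln = make_alignment(
            seq,
            [("r1", "g", with_ins, 0), ("r2", "g", with_ins, 0)]
            + [("r3", "g", without, 0), ("r4", "g", without, 0)],
        )
        cols = detect_potential_snps(aln)
        assert len(cols) == 1
        assert cols[0].is_indel_column

    def test_per_genotype_support_mode(self):
        seq = "ACGTACGTAC"
        alt = seq[:4] + "G" + seq[5:]
        aln = make_alignment(
            seq,
            [("r1", "g1", seq, 0), ("r2", "g1", seq, 0)]
            + [("r3", "g1", alt, 0), ("r4", "g2", alt, 0)],
        )
        assert len(detect_potential_snps(aln)) == 1  # overall: 2 alt reads
        assert detect_potential_snps(aln, per_genotype=True) == []


class TestHaplotypes:
    def test_one_column_three_three_gives_two_haplotypes(self):
        aln = uniform_alignment("ACGTACGTACGT", {5: "T"}, n_each=3)
        cols = detect_potential_snps(aln)
        haps = reconstruct_haplotypes(aln, cols)
        assert len(haps) == 2
        assert sorted(h.n_members for h in haps) == [3, 3]

    def test_zero_columns_gives_single_haplotype(self):
        seq = "ACGTACGTACGT"
        aln = make_alignment(seq, [("r%d" % i, "g", seq, 0) for i in range(4)])
        haps = reconstruct_haplotypes(aln, [])
        assert len(haps) == 1
        assert haps[0].n_members == 4

    def test_partial_read_merges_into_unique_compatible(self):
        seq = "ACGTACGTACGT"
        alt = seq[:2] + "G" + seq[3:5] + "T" + seq[6:]
        rows = [("a%d" % i, "g", seq, 0) for i in range(2)]
        rows += [("b%d" % i, "g", alt, 0) for i in range(2)]
        rows.append(("part", "g", alt[6:], 6))  # covers no variant column
        aln = make_alignment(seq, rows)
        cols = detect_potential_snps(aln)
        haps = reconstruct_haplotypes(aln, cols)
        assert len(haps) == 2
        assert sum(h.n_members for h in haps) == 5

    def test_recovered_count_matches_truth_on_simulated_contigs(self, small_sim):
        tr = small_sim["transcriptome"]
        genes = tr.gene_by_id()
        for aln in small_sim["contigs"]:
            cols = detect_potential_snps(aln)
            haps = reconstruct_haplotypes(aln, cols)
            positions = [c.position for c in cols if not c.is_indel_column]
            gene = genes[aln.contig_id]
            true_vectors = {
                tuple(copy[p - 1] for p in positions)
                for copies in gene.alleles.values()
                for copy in copies
            }
            assert len(haps) == len(true_vectors)


class TestDValue:
    def col(self, pos, counts):
        return VariantColumn("c", pos, pos - 1, {"g": counts})

    def test_single_haplotype_is_zero(self):
        assert d_value([Haplotype(0, ["A"])], [self.col(5, {"A": 3, "G": 2})]) == 0.0

    def test_no_columns_is_zero(self):
        assert d_value([Haplotype(0, []), Haplotype(1, [])], []) == 0.0

    def test_hand_computed_three_haplotype_case(self):
        haps = [
            Haplotype(0, ["A", "A"], member_read_ids=["a", "b", "c"]),
            Haplotype(1, ["A", "G"], member_read_ids=["d", "e"]),
            Haplotype(2, ["G", "G"], member_read_ids=["f"]),
        ]
        cols = [self.col(10, {"A": 5, "G": 1}), self.col(60, {"A": 4, "G": 2})]
        # divergences from majority: (0, 1, 2) over m=2 -> f = (0, .5, 1)
        expected = math.sqrt(((0 - 0.5) ** 2 + 0 + (1 - 0.5) ** 2) / 3)
        assert d_value(haps, cols) == pytest.approx(expected)

    def test_invariant_under_relabeling(self):
        haps = [
            Haplotype(0, ["A", "A"], member_read_ids=["a", "b"]),
            Haplotype(1, ["G", "G"], member_read_ids=["c", "d"]),
        ]
        cols = [self.col(10, {"A": 2, "G": 2}), self.col(60, {"A": 2, "G": 2})]
        d1 = d_value(haps, cols)
        d2 = d_value(list(reversed(haps)), cols)
        assert d1 == pytest.approx(d2)


class TestClassify:
    def test_heterozygous_within_one_genotype_is_intra(self):
        col = VariantColumn("c", 5, 4, {"g1": {"A": 3, "G": 3}})
        assert classify_snp(col) == ("intra", False)

    def test_fixed_difference_between_genotypes_is_inter(self):
        col = VariantColumn(
            "c", 5, 4, {"g1": {"G": 3}, "g2": {"G": 2}, "g3": {"G": 4}, "g4": {"A": 3}}
        )
        assert classify_snp(col) == ("inter", False)

    def test_both_patterns_reports_inter_with_flag(self):
        col = VariantColumn("c", 5, 4, {"g1": {"A": 3, "G": 3}, "g2": {"G": 4}, "g3": {"A": 2}})
        snp_class, both = classify_snp(col)
        assert snp_class == "inter" and both

    def test_single_genotype_cannot_be_inter(self):
        col = VariantColumn("c", 5, 4, {"g1": {"A": 5, "G": 4}})
        assert classify_snp(col)[0] == "intra"


class TestFilterReliable:
    def clean_contig(self, pos=60, length=160, alt="G"):
        """Contig with one variant at ``pos`` (1-based), clean elsewhere."""
        import numpy as np

        rng = np.random.default_rng(99)
        while True:
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
            if all(len(set(seq[i : i + 3])) > 1 for i in range(length - 2)):
                break  # no homopolymer run of 3+
        if seq[pos - 1] == alt:
            alt = "C" if alt != "C" else "T"
        alt_seq = seq[: pos - 1] + alt + seq[pos:]
        aln = make_alignment(
            seq,
            [("r%d" % i, "g", seq, 0) for i in range(3)]
            + [("s%d" % i, "g", alt_seq, 0) for i in range(3)],
        )
        return aln

    def test_clean_snp_passes(self):
        aln = self.clean_contig()
        cols = detect_potential_snps(aln)
        assert filter_reliable(cols[0], aln, cols) == ("pass", None)

    def test_snp_adjacent_to_homopolymer_fails(self):
        seq = "ACGTACGTAC" * 5 + "AAAA" + "CGTACGTACG" * 5 + "ACGTACGTACGTACGT"
        pos = 55  # immediately after the AAAA run
        alt_seq = seq[: pos - 1] + "T" + seq[pos:]
        assert seq[pos - 1] == "C"
        aln = make_alignment(
            seq,
            [("r%d" % i, "g", seq, 0) for i in range(3)]
            + [("s%d" % i, "g", alt_seq, 0) for i in range(3)],
        )
        cols = detect_potential_snps(aln)
        verdict, reason = filter_reliable(cols[0], aln, cols)
        assert (verdict, reason) == ("fail", "homopolymer")

    def test_second_snp_within_50bp_fails_dirty_flank(self):
        aln = self.clean_contig()
        cols = detect_potential_snps(aln)
        other = VariantColumn("c1", cols[0].position + 30, 0, {"g": {"A": 2, "G": 2}})
        verdict, reason = filter_reliable(cols[0], aln, cols + [other])
        assert (verdict, reason) == ("fail", "dirty_flank")

    def test_snp_near_contig_end_fails_short_flank(self):
        aln = self.clean_contig(pos=40)
        cols = detect_potential_snps(aln)
        verdict, reason = filter_reliable(cols[0], aln, cols)
        assert (verdict, reason) == ("fail", "short_flank")

    def test_low_mean_quality_fails_when_quals_given(self):
        aln = self.clean_contig()
        cols = detect_potential_snps(aln)
        quals = {m.read_id: [0.5] * len(m.aligned) for m in aln.members}  # Q3
        verdict, reason = filter_reliable(cols[0], aln, cols, read_quals=quals)
        assert (verdict, reason) == ("fail", "low_quality")


class TestCeilingAndChimera:
    @pytest.mark.parametrize("n,p,expected", [(4, 2, 8), (1, 1, 1), (3, 4, 12)])
    def test_ceiling_is_genotypes_times_ploidy(self, n, p, expected):
        assert haplotype_ceiling(n, p) == expected

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            haplotype_ceiling(0, 2)

    @pytest.mark.parametrize("h,flagged", [(9, True), (8, False)])
    def test_flag_is_strict_inequality(self, h, flagged):
        rep = ContigSnpReport("c", 5, h, 0.1)
        assert flag_chimera(rep, 8).chimera_flag is flagged

    def test_flagged_contig_yields_no_markers_by_default(self):
        aln = TestFilterReliable().clean_contig()
        cols = detect_potential_snps(aln)
        marker = extract_marker(aln, cols[0], "intra", 0.0, 9)
        rep = ContigSnpReport("c", 1, 9, 0.1, markers=[marker])
        assert flag_chimera(rep, 8).markers == []
        rep2 = ContigSnpReport("c", 1, 9, 0.1, markers=[marker])
        assert flag_chimera(rep2, 8, keep_chimeric=True).markers == [marker]


class TestExtractMarker:
    def test_flank_is_101bp_centred_on_snp(self):
        aln = TestFilterReliable().clean_contig(pos=60, length=160)
        cols = detect_potential_snps(aln)
        m = extract_marker(aln, cols[0], "intra", 0.2, 4)
        assert len(m.flank_seq) == 101
        assert m.flank_seq == aln.ungapped_consensus[9:110]
        assert m.flank_seq[50] == aln.ungapped_consensus[59]
        assert m.position == 60

    def test_insufficient_flank_raises(self):
        aln = TestFilterReliable().clean_contig(pos=40)
        cols = detect_potential_snps(aln)
        with pytest.raises(ValueError):
            extract_marker(aln, cols[0], "intra", 0.0, 2)
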