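"""Seed-and-extend search, Karlin-Altschul E-values, marker uniqueness filter."""

import copy
import math

import numpy as np
import pytest
from Bio import Align

from snpmine.seqio import MarkerRecord
from snpmine.unique import (
    ScoringParams,
    build_index,
    filter_unique,
    hit_histogram,
    revcomp,
    search,
)


@pytest.fixture(scope="module")
def toy_db():
    rng = np.random.default_rng(7)
    contigs = {f"c{i}": "".join("ACGT"[x] for x in rng.integers(0, 4, 400)) for i in range(4)}
    # add a 95%-identity paralog of c0
    par = list(contigs["c0"])
    for p in rng.choice(400, 20, replace=False):
        par[p] = "ACGT"[rng.integers(0, 4)]
    contigs["c0_paralog"] = "".join(par)
    return contigs


@pytest.fixture(scope="module")
def toy_index(toy_db):
    return build_index(toy_db)


def oracle_aligner():
    sp = ScoringParams()
    a = Align.PairwiseAligner(
        mode="local",
        match_score=sp.match,
        mismatch_score=sp.mismatch,
        open_gap_score=sp.gap_open,
        extend_gap_score=sp.gap_extend,
    )
    return a, sp


class TestIndex:
    def test_seed_count_for_single_contig(self):
        idx = build_index({"c": "A" * 100}, word_size=11)
        fwd = [e for e in idx.table.get("A" * 11, []) if e[1] == "+"]
        assert len(fwd) == 90  # L - w + 1

    def test_contig_shorter_than_word_gives_no_seeds(self):
        idx = build_index({"c": "ACGT"}, word_size=11)
        assert idx.table == {}

    def test_absent_word_lookup_is_empty(self, toy_index):
        assert toy_index.table.get("N" * 11, []) == []

    def test_word_size_floor(self):
        with pytest.raises(ValueError):
            build_index({"c": "ACGTACGT"}, word_size=3)


class TestSearch:
    def test_flank_hits_its_source_contig_far_below_threshold(self, toy_db, toy_index):
        q = toy_db["c1"][100:201]
        hits = search(q, toy_index)
        best = hits[0]
        assert best.contig_id == "c1"
        assert best.e_value < 1e-20
        assert best.identity == 1.0

    def test_reverse_complement_query_scores_identically(self, toy_db, toy_index):
        q = toy_db["c2"][50:151]
        e_fwd = search(q, toy_index)[0].e_value
        e_rev = search(revcomp(q), toy_index)[0].e_value
        assert e_fwd == pytest.approx(e_rev)

    def test_hits_sorted_by_evalue(self, toy_db, toy_index):
        q = toy_db["c0"][150:251]
        hits = search(q, toy_index)
        evals = [h.e_value for h in hits]
        assert evals == sorted(evals)

    def test_matches_exhaustive_smith_waterman_on_toy_database(self, toy_db, toy_index):
        """Retain/discard decisions at E<=1e-20 equal a full scan of every
        contig with the same scoring."""
        aligner, sp = oracle_aligner()
        rng = np.random.default_rng(3)
        n_db = toy_index.total_length
        for _ in range(25):
            cid = list(toy_db)[rng.integers(0, len(toy_db))]
            s = toy_db[cid]
            start = rng.integers(0, len(s) - 101)
            q = s[start : start + 101]
            mine = {h.contig_id for h in search(q, toy_index) if h.e_value <= 1e-20}
            oracle = set()
            for ocid, oseq in toy_db.items():
                score = max(aligner.score(q, oseq), aligner.score(q, revcomp(oseq)))
                if sp.evalue(score, len(q), n_db) <= 1e-20:
                    oracle.add(ocid)
            assert mine == oracle


class TestEvalueStatistics:
    def test_evalue_decreases_with_score(self):
        sp = ScoringParams()
        es = [sp.evalue(s, 101, 10_000) for s in range(10, 100, 10)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_doubling_database_doubles_evalue(self):
        sp = ScoringParams()
        assert sp.evalue(60, 101, 20_000) == pytest.approx(2 * sp.evalue(60, 101, 10_000))


class TestFilterUnique:
    def marker(self, db, cid="c1", pos=150):
        return MarkerRecord(
            f"{cid}:{pos}", cid, pos, ("A", "G"), "inter", 0.0, 2, db[cid][pos - 51 : pos + 50]
        )

    def test_unique_marker_retained(self, toy_db, toy_index):
        m = self.marker(toy_db)
        hits = {m.marker_id: search(m.flank_seq, toy_index, m.marker_id)}
        kept, ledger = filter_unique([m], hits)
        assert kept == [m] and ledger == []
        assert m.status[-1] == ("unique", "pass")

    def test_duplicated_contig_causes_multi_hit_discard(self, toy_db):
        db = dict(toy_db)
        db["c1_dup"] = db["c1"]
        idx = build_index(db)
        m = self.marker(db)
        hits = {m.marker_id: search(m.flank_seq, idx, m.marker_id)}
        kept, ledger = filter_unique([m], hits)
        assert kept == []
        assert ledger[0]["reason"] == "multi_hit"

    def test_hit_on_foreign_contig_only_is_wrong_contig(self, toy_db, toy_index):
        m = self.marker(toy_db, cid="c1")
        relabelled = MarkerRecord(
            m.marker_id, "c2", m.position, m.alleles, m.snp_class, 0.0, 2, m.flank_seq
        )
        hits = {m.marker_id: search(m.flank_seq, toy_index, m.marker_id)}
        kept, ledger = filter_unique([relabelled], hits)
        assert ledger[0]["reason"] == "wrong_contig"

    def test_idempotent_and_order_independent(self, toy_db, toy_index):
        ms = [self.marker(toy_db, "c1", 150), self.marker(toy_db, "c2", 200)]
        hits = {m.marker_id: search(m.flank_seq, toy_index, m.marker_id) for m in ms}
        kept1, _ = filter_unique(copy.deepcopy(ms), hits)
        kept2, _ = filter_unique(list(reversed(copy.deepcopy(ms))), hits)
        assert {m.marker_id for m in kept1} == {m.marker_id for m in kept2}
        again, _ = filter_unique(copy.deepcopy(kept1), hits)
        assert {m.marker_id for m in again} == {m.marker_id for m in kept1}


class TestHistogram:
    def test_all_unique_markers_land_in_bin_one(self, toy_db, toy_index):
        ms = [
            MarkerRecord(
                f"c{i}:150", f"c{i}", 150, ("A", "G"), "inter", 0.0, 2,
                toy_db[f"c{i}"][99:200],
            )
            for i in (1, 2, 3)
        ]
        hits = {m.marker_id: search(m.flank_seq, toy_index, m.marker_id) for m in ms}
        hist = hit_histogram(ms, hits)
        assert hist["bins"]["1"] == 3
        assert hist["unique_pct"] == 100.0

    def test_empty_marker_set(self):
        hist = hit_histogram([], {})
        assert hist["n_markers"] == 0 and hist["unique_fraction"] == 0.0
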