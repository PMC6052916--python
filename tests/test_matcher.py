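"""Seed-and-extend matcher vs. the exhaustive oracle, and database screening."""

import numpy as np
import pytest

import pirnascreen as ps
from pirnascreen.matcher import MatchParams, ReferenceSet, build_seed_index

from conftest import random_dna


def _mutate_at(seq, pos, rng):
    alt = [b for b in "ACGT" if b != seq[pos]]
    return seq[:pos] + str(rng.choice(alt)) + seq[pos + 1 :]


class TestSeedIndex:
    def test_key_count_sliding_window(self):
        rs = ReferenceSet("tRNA", [ps.SeqRecord("r", "ACGTACGTACGTACGTACGTA")])
        build_seed_index(rs, 19)
        assert len(rs.seed_index) == 3  # 21 - 19 + 1 distinct windows

    def test_reference_equal_to_seed_gets_one_key(self):
        rs = ReferenceSet("tRNA", [ps.SeqRecord("r", "A" * 19)])
        build_seed_index(rs, 19)
        assert len(rs.seed_index) == 1

    def test_homopolymer_repeats_collapse_to_one_key(self):
        rs = ReferenceSet("tRNA", [ps.SeqRecord("r", "A" * 25)])
        build_seed_index(rs, 19)
        assert len(rs.seed_index) == 1
        assert len(rs.seed_index["A" * 19]) == 7

    def test_short_reference_warned_and_skipped(self):
        rs = ReferenceSet("tRNA", [ps.SeqRecord("short", "ACGTACGT")])
        with pytest.warns(UserWarning, match="short"):
            build_seed_index(rs, 19)
        assert rs.unindexed == [0]

    def test_n_kmers_excluded(self):
        rs = ReferenceSet("tRNA", [ps.SeqRecord("r", "A" * 19 + "N" + "A" * 5)])
        build_seed_index(rs, 19)
        assert all("N" not in k for k in rs.seed_index)


class TestFindHits:
    def test_exact_embedding_found_at_offset(self, yrna_refset):
        ref = yrna_refset.records[0].seq
        q = ps.SeqRecord("q", ref[66:92])
        (hit,) = ps.find_hits(q, yrna_refset, MatchParams(max_mismatches=0))
        assert (hit.ref_start, hit.mismatches, hit.coverage) == (66, 0, 1.0)
        assert hit.ref_start_1based == 67  # human-readable start

    def test_substitution_needs_mm1(self, yrna_refset):
        # substitution at position 3 leaves the exact 19-mer seed on its right
        rng = np.random.default_rng(0)
        ref = yrna_refset.records[0].seq
        q = ps.SeqRecord("q", _mutate_at(ref[66:92], 3, rng))
        assert ps.find_hits(q, yrna_refset, MatchParams(max_mismatches=0, min_coverage=1.0)) == []
        (hit,) = ps.find_hits(q, yrna_refset, MatchParams(max_mismatches=1, min_coverage=1.0))
        assert hit.mismatches == 1
        assert hit.mismatch_positions == (3,)

    def test_mid_query_substitution_destroys_every_seed(self, yrna_refset):
        # a central substitution in a 26-mer leaves no exact 19-mer: the
        # seeded path goes blind while the oracle still finds the placement
        rng = np.random.default_rng(0)
        ref = yrna_refset.records[0].seq
        q = ps.SeqRecord("q", _mutate_at(ref[66:92], 12, rng))
        params = MatchParams(max_mismatches=1, min_coverage=1.0)
        assert ps.find_hits(q, yrna_refset, params) == []
        (hit,) = ps.brute_force_hits(q, yrna_refset, params)
        assert hit.mismatches == 1

    def test_end_trimming_recovers_overhanging_query(self, yrna_refset):
        # 32-mer whose final base overhangs a 31-nt exact sub-match
        ref = yrna_refset.records[0].seq
        q = ps.SeqRecord("q", ref[81:112] + "A" if ref[111] != "A" else ref[81:112] + "C")
        params = MatchParams(max_mismatches=0, min_coverage=0.94)
        hits = ps.find_hits(q, yrna_refset, params)
        assert hits == ps.brute_force_hits(q, yrna_refset, params)
        best = hits[0]
        assert best.coverage == pytest.approx(31 / 32)
        assert best.mismatches == 0

    def test_query_shorter_than_seed_uses_exhaustive_path(self, yrna_refset):
        ref = yrna_refset.records[0].seq
        q = ps.SeqRecord("q", ref[10:26])  # 16 nt < seed 19
        params = MatchParams(max_mismatches=0)
        assert ps.find_hits(q, yrna_refset, params) == ps.brute_force_hits(
            q, yrna_refset, params
        )
        assert ps.find_hits(q, yrna_refset, params)[0].ref_start == 10

    def test_reverse_strand_hit(self, yrna_refset):
        from pirnascreen.records import reverse_complement

        ref = yrna_refset.records[0].seq
        q = ps.SeqRecord("q", reverse_complement(ref[40:66]))
        assert ps.find_hits(q, yrna_refset, MatchParams(max_mismatches=0)) == []
        (hit,) = ps.find_hits(
            q, yrna_refset, MatchParams(max_mismatches=0, strand_mode="both")
        )
        assert (hit.strand, hit.ref_start, hit.ref_end) == ("-", 40, 66)

    def test_mm1_hits_superset_of_mm0(self, yrna_refset):
        rng = np.random.default_rng(1)
        ref = yrna_refset.records[0].seq
        for pos in (3, 13, 22):
            q = ps.SeqRecord("q", _mutate_at(ref[20:50], pos, rng))
            h0 = set(ps.find_hits(q, yrna_refset, MatchParams(max_mismatches=0)))
            h1 = set(ps.find_hits(q, yrna_refset, MatchParams(max_mismatches=1)))
            assert h0 <= h1

    def test_lower_coverage_hits_superset(self, yrna_refset):
        ref = yrna_refset.records[0].seq
        q = ps.SeqRecord("q", ref[100:112] + random_dna(np.random.default_rng(2), 14))
        loose = {
            (h.reference_id, h.ref_start, h.ref_end)
            for h in ps.find_hits(q, yrna_refset, MatchParams(max_mismatches=0, min_coverage=0.45))
        }
        tight = {
            (h.reference_id, h.ref_start, h.ref_end)
            for h in ps.find_hits(q, yrna_refset, MatchParams(max_mismatches=0, min_coverage=0.9))
        }
        assert tight <= loose


def _aligned_region_has_exact_seed(hit, query, refset, seed_len):
    """True when the alignment contains >= seed_len consecutive matches."""
    ref = {r.id: r.seq for r in refset.records}[hit.reference_id]
    qseq = query.seq
    if hit.strand == "-":
        from pirnascreen.records import reverse_complement

        qseq = reverse_complement(qseq)
        q0 = len(qseq) - hit.query_end
    else:
        q0 = hit.query_start
    run = best = 0
    for i in range(hit.aligned_length):
        if qseq[q0 + i] == ref[hit.ref_start + i] and qseq[q0 + i] != "N":
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best >= seed_len


class TestOracleEquivalence:
    def test_exact_plant_identical_hit_lists(self, yrna_refset):
        ref = yrna_refset.records[0].seq
        q = ps.SeqRecord("q", ref[30:58])
        params = MatchParams(max_mismatches=0)
        assert ps.find_hits(q, yrna_refset, params) == ps.brute_force_hits(
            q, yrna_refset, params
        )

    def test_two_mismatches_under_mm1_empty_from_both(self, yrna_refset):
        rng = np.random.default_rng(3)
        ref = yrna_refset.records[0].seq
        q = ps.SeqRecord("q", _mutate_at(_mutate_at(ref[20:48], 5, rng), 20, rng))
        params = MatchParams(max_mismatches=1, min_coverage=1.0)
        assert ps.find_hits(q, yrna_refset, params) == []
        assert ps.brute_force_hits(q, yrna_refset, params) == []

    def test_fuzzed_equivalence_when_seed_survives(self):
        """Seeded 200-case fuzz: find_hits ⊆ oracle always, equal when a 19-mer survives."""
        rng = np.random.default_rng(42)
        n_checked = 0
        for case in range(200):
            ref_len = int(rng.integers(60, 201))
            ref = random_dna(rng, ref_len)
            refset = ReferenceSet("tRNA", [ps.SeqRecord(f"r{case}", ref)])
            qlen = int(rng.integers(24, 36))
            if rng.random() < 0.8:  # planted query
                off = int(rng.integers(0, ref_len - qlen + 1))
                q = ref[off : off + qlen]
            else:
                q = random_dna(rng, qlen)
            for _ in range(int(rng.integers(0, 3))):
                q = _mutate_at(q, int(rng.integers(0, qlen)), rng)
            query = ps.SeqRecord("q", q)
            params = MatchParams(
                max_mismatches=int(rng.integers(0, 2)),
                min_coverage=float(rng.choice([0.94, 1.0])),
            )
            found = ps.find_hits(query, refset, params)
            oracle = ps.brute_force_hits(query, refset, params)
            assert set(found) <= set(oracle)
            for hit in oracle:
                if _aligned_region_has_exact_seed(hit, query, refset, params.seed_len):
                    assert hit in found
                    n_checked += 1
        assert n_checked > 50  # the fuzz actually exercised seeded recovery


class TestScreenDatabase:
    def test_single_attribution_counts_once(self):
        rng = np.random.default_rng(9)
        shared = random_dna(rng, 30)
        refsets = [
            ReferenceSet("tRNA", [ps.SeqRecord("t1", shared + random_dna(rng, 40))]),
            ReferenceSet("rRNA", [ps.SeqRecord("r1", random_dna(rng, 40) + shared)]),
        ]
        queries = ps.QuerySet("db", [ps.SeqRecord("q", shared[:26])])
        table = ps.screen_database(queries, refsets, MatchParams(max_mismatches=0))
        assert table.total == 1
        assert sum(table.counts.values()) == 1
        assert table.counts["rRNA"] == 1  # class priority: rRNA before tRNA

    def test_multi_count_mode_counts_every_class(self):
        rng = np.random.default_rng(9)
        shared = random_dna(rng, 30)
        refsets = [
            ReferenceSet("tRNA", [ps.SeqRecord("t1", shared + random_dna(rng, 40))]),
            ReferenceSet("rRNA", [ps.SeqRecord("r1", random_dna(rng, 40) + shared)]),
        ]
        queries = ps.QuerySet("db", [ps.SeqRecord("q", shared[:26])])
        table = ps.screen_database(
            queries, refsets, MatchParams(max_mismatches=0), multi_count=True
        )
        assert table.total == 1
        assert table.counts == {"tRNA": 1, "rRNA": 1}

    def test_zero_refsets_all_counts_zero(self, plasma_queryset):
        table = ps.screen_database(plasma_queryset, [], MatchParams())
        assert table.total == 0 and table.counts == {}

    def test_duplicate_class_labels_rejected(self, yrna_refset):
        other = ReferenceSet("YRNA", list(yrna_refset.records))
        with pytest.raises(ps.matcher.ConfigurationError):
            ps.screen_database(ps.QuerySet("db", []), [yrna_refset, other], MatchParams())

    def test_percent_formula_rendering(self):
        assert ps.percent_overlap(40, 1000) == 4.0
        assert ps.percent_overlap(0, 0) == 0.0
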