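"""Window enumeration, isoform expansion, exact scanning, specificity."""

import random

import pytest

from conserved16s import (
    PrimerContig,
    SequenceRecord,
    contig_iso_totals,
    enumerate_windows,
    expand_isoforms,
    scan_database,
    sequence_multiplicity,
    specificity_analysis,
)
from conserved16s.kmer_engine import _select_inflection

from conftest import make_records


def brute_force_scan(windows, records):
    """Independent oracle: per-record, per-isoform substring search."""
    out = []
    for w in windows:
        isoforms = set(expand_isoforms(w.sequence))
        hits = {}
        for rec in records:
            positions = [
                i
                for i in range(len(rec.sequence) - w.k + 1)
                if rec.sequence[i : i + w.k] in isoforms
            ]
            if positions:
                hits[rec.id] = positions
        out.append(hits)
    return out


class TestEnumerateWindows:
    def test_window_count_is_length_minus_k_plus_one(self, contig_by_name):
        assert len(enumerate_windows(contig_by_name["1"], 12)) == 9

    def test_contig_equal_to_k_yields_itself(self):
        c = PrimerContig(name="x", sequence="ACGTACGTACGT", ecoli_start=1, ecoli_end=12)
        windows = enumerate_windows(c, 12)
        assert len(windows) == 1 and windows[0].sequence == c.sequence

    def test_zero_based_indexing_matches_reported_windows(self, contig_by_name):
        """Window numbering starts at 0: the 9th window of contig 1 has
        index 8, and the named high-frequency windows sit at their reported
        indices."""
        w1 = enumerate_windows(contig_by_name["1"], 12)
        assert w1[8].sequence == "ATYMTGGCTCAG"
        w3 = enumerate_windows(contig_by_name["3"], 12)
        assert w3[25].sequence == "GGRNGGCNGCAG"
        w5b = enumerate_windows(contig_by_name["5b"], 12)
        assert w5b[10].sequence == "TAGAWACCCNNG"

    def test_contig_shorter_than_k_yields_no_windows(self, contig_by_name):
        assert enumerate_windows(contig_by_name["6b"], 17) == []

    def test_nonpositive_k_rejected(self, contig_by_name):
        with pytest.raises(ValueError):
            enumerate_windows(contig_by_name["1"], 0)


class TestExpandIsoforms:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("ACGT", {"ACGT"}),
            ("AK", {"AG", "AT"}),
            ("RY", {"AC", "AT", "GC", "GT"}),
        ],
    )
    def test_examples(self, seq, expected):
        assert set(expand_isoforms(seq)) == expected

    def test_deterministic_lexicographic_order(self):
        assert expand_isoforms("NR") == sorted(expand_isoforms("NR"))

    def test_count_matches_multiplicity_for_all_reference_windows(self, contigs):
        for c in contigs:
            for w in enumerate_windows(c, 12):
                assert len(expand_isoforms(w.sequence)) == sequence_multiplicity(
                    w.sequence
                )


class TestContigIsoTotals:
    @pytest.mark.parametrize(
        "name, n_kmers, n_iso",
        [("4", 21, 970), ("2", 9, 61), ("6b", 5, 5)],
    )
    def test_per_contig_window_and_isoform_counts(
        self, contig_by_name, name, n_kmers, n_iso
    ):
        s = contig_iso_totals(contig_by_name[name], 12)
        assert (s.n_kmers, s.n_iso_kmers) == (n_kmers, n_iso)

    def test_overall_totals(self, contigs):
        totals = [contig_iso_totals(c, 12) for c in contigs]
        assert sum(s.n_kmers for s in totals) == 223
        assert sum(s.n_iso_kmers for s in totals) == 2886


class TestScanDatabase:
    def test_degenerate_window_hits_via_isoform(self):
        """'RGAT' (isoforms AGAT/GGAT) must hit records 1 and 3 only."""
        c = PrimerContig(name="t", sequence="RGAT", ecoli_start=1, ecoli_end=4)
        records = make_records("CCAGATCC", "CCCCCCCC", "GGATGGAT")
        [res] = scan_database(enumerate_windows(c, 4), records)
        assert res.seq_hits == 2
        assert set(res.hit_positions) == {"r1", "r3"}
        # r3 matches twice but is counted once
        assert res.hit_positions["r3"] == [0, 4]
        assert res.n_duplicate_records == 1

    def test_absent_window_scores_zero(self):
        c = PrimerContig(name="t", sequence="AAAA", ecoli_start=1, ecoli_end=4)
        [res] = scan_database(enumerate_windows(c, 4), make_records("CCCCCC"))
        assert res.seq_hits == 0 and res.percent == 0.0

    def test_empty_database_rejected(self):
        c = PrimerContig(name="t", sequence="AAAA", ecoli_start=1, ecoli_end=4)
        with pytest.raises(ValueError, match="empty"):
            scan_database(enumerate_windows(c, 4), [])

    def test_empty_window_list_yields_empty_result(self):
        assert scan_database([], make_records("ACGT")) == []

    def test_matches_brute_force_oracle_on_random_databases(self, contig_by_name):
        rng = random.Random(42)
        records = [
            SequenceRecord(
                id=f"r{i}",
                sequence="".join(rng.choice("ACGT") for _ in range(rng.randint(40, 400))),
            )
            for i in range(100)
        ]
        # plant a couple of isoforms so hits exist
        iso = expand_isoforms(contig_by_name["3"].sequence[25:37])[0]
        records[5] = SequenceRecord(id="r5", sequence=records[5].sequence + iso)
        records[9] = SequenceRecord(id="r9", sequence=iso + records[9].sequence + iso)
        windows = enumerate_windows(contig_by_name["3"], 12)
        results = scan_database(windows, records)
        expected = brute_force_scan(windows, records)
        for res, exp in zip(results, expected):
            assert res.seq_hits == len(exp)
            assert res.hit_positions == exp

    def test_recorded_positions_slice_to_isoforms(self, small_db):
        records, _ = small_db
        c = PrimerContig(name="t", sequence="GGRNGGCNGCAG", ecoli_start=1, ecoli_end=12)
        [res] = scan_database(enumerate_windows(c, 12), records)
        isoforms = set(expand_isoforms(c.sequence))
        by_id = {r.id: r.sequence for r in records}
        for rid, positions in res.hit_positions.items():
            for p in positions:
                assert by_id[rid][p : p + 12] in isoforms

    def test_hits_never_increase_with_k_at_fixed_anchor(self, small_db, contig_by_name):
        """Growing a window rightward from the same start can only lose hits."""
        records, _ = small_db
        c = contig_by_name["3"]
        for k in range(9, 15):
            w_short = enumerate_windows(c, k)[0]
            w_long = enumerate_windows(c, k + 1)[0]
            [short], [long_] = (
                scan_database([w], records) for w in (w_short, w_long)
            )
            assert long_.seq_hits <= short.seq_hits

    def test_mixed_window_sizes_rejected(self, contig_by_name):
        w9 = enumerate_windows(contig_by_name["3"], 9)[:1]
        w12 = enumerate_windows(contig_by_name["3"], 12)[:1]
        with pytest.raises(ValueError, match="share one k"):
            scan_database(w9 + w12, make_records("ACGT" * 10))


class TestSpecificity:
    def test_single_planted_occurrence_gives_zero_duplicates(self, contig_by_name):
        c = contig_by_name["6b"]
        records = make_records("CC" + c.sequence + "TT", "AA" + c.sequence)
        curve = specificity_analysis(c, records, range(9, 16))
        assert curve.duplicate_counts == [0] * 7

    def test_planted_double_occurrence_counted_once_as_hit_once_as_duplicate(self):
        c = PrimerContig(name="t", sequence="ACGTACGTACGTT", ecoli_start=1, ecoli_end=13)
        window = enumerate_windows(c, 12)[0]
        rec = make_records("ACGTACGTACGT" + "CCCC" + "ACGTACGTACGT")
        [res] = scan_database([window], rec)
        assert res.seq_hits == 1
        assert res.n_duplicate_records == 1
        curve = specificity_analysis(c, rec, [12])
        assert curve.duplicate_counts == [1]

    def test_duplicate_counts_non_increasing_on_synthetic_databases(self, small_db):
        records, _ = small_db
        for name_seq in [
            "ACTGAGAYACGGYCCARACTCCTACGGRNGGCNGCAGTRRGGAA",  # contig 3
            "GTGTAGMGGTGAAATKCGTAGAT",  # contig 5a
            "GGAAGGYGGGGAYGACG",  # contig 8a
        ]:
            c = PrimerContig(
                name="t", sequence=name_seq, ecoli_start=1, ecoli_end=len(name_seq)
            )
            curve = specificity_analysis(c, records, range(9, 16))
            d = curve.duplicate_counts
            assert all(a >= b for a, b in zip(d, d[1:]))

    def test_k_range_exceeding_contig_rejected(self, contig_by_name):
        with pytest.raises(ValueError):
            specificity_analysis(contig_by_name["6b"], make_records("ACGT"), range(9, 20))

    def test_inflection_rule(self):
        # convex kink at k=11
        assert _select_inflection([9, 10, 11, 12, 13], [100, 60, 25, 20, 18]) == 11
        # flat curve falls back to 12
        assert _select_inflection([9, 10, 11, 12, 13], [5, 5, 5, 5, 5]) == 12
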