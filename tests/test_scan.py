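import numpy as np
import pytest

from conftest import brute_find, brute_pairs, random_dna
from spacerscan.examples import SPACER_14_EXAMPLE, SPACER_24_EXAMPLE
from spacerscan.scan import (
    MotifPairQuery,
    collect_spacers,
    find_motif,
    profile,
    scan_pairs,
)
from spacerscan.sequence_io import reverse_complement


class TestFindMotif:
    @pytest.mark.parametrize(
        "seq,motif,expected",
        [
            ("AAAAG", "AAAG", [1]),
            ("ACGTACGT", "ACGT", [0, 4]),
            ("AAAAAG", "AAAG", [2]),
            ("AAAAAA", "AA", [0, 1, 2, 3, 4]),  # overlaps all count
            ("ACG", "ACGT", []),
        ],
    )
    def test_known_positions(self, seq, motif, expected):
        assert find_motif(seq, motif) == expected
        assert find_motif(seq, motif) == brute_find(seq, motif)

    def test_ambiguity_code_never_matches(self):
        assert find_motif("AANG", "AAAG") == []
        assert find_motif("NAAAGN", "AAAG") == [1]

    def test_empty_motif_rejected(self):
        with pytest.raises(ValueError):
            find_motif("ACGT", "")


class TestScanPairs:
    def test_adjacent_pair_zero_spacer(self, default_query):
        hits = scan_pairs("AAAGACGT", default_query)
        assert len(hits) == 1
        assert (hits[0].spacer_len, hits[0].spacer_seq) == (0, "")

    def test_published_24bp_spacer_example(self, default_query):
        hits = scan_pairs(SPACER_24_EXAMPLE, default_query)
        assert len(hits) == 1
        assert hits[0].spacer_len == 24

    def test_published_14bp_spacer_example(self, default_query):
        hits = scan_pairs(SPACER_14_EXAMPLE, default_query.reversed_orientation())
        assert len(hits) == 1
        assert hits[0].spacer_len == 14

    def test_one_left_occurrence_two_hits(self, default_query):
        hits = scan_pairs("AAAGAAAGACGT", default_query)
        assert {h.spacer_len for h in hits} == {0, 4}

    def test_hit_reconstructs_source(self, default_query, rng):
        seq = random_dna(rng, 3000)
        q = default_query
        for h in scan_pairs(seq, q):
            span = q.left_motif + h.spacer_seq + q.right_motif
            assert seq[h.left_start : h.left_start + len(span)] == span

    def test_exclusive_mode_drops_nested_motifs(self):
        # spacer of the wide hit contains the inner AAAG occurrence
        seq = "AAAGTTAAAGTTACGT"
        q = MotifPairQuery("AAAG", "ACGT", 0, 30)
        all_hits = scan_pairs(seq, q)
        excl = scan_pairs(seq, q, exclusive=True)
        assert len(all_hits) == 2
        assert len(excl) == 1
        assert excl[0].left_start == 6

    def test_matches_bruteforce_on_random_sequences(self, default_query, rng):
        for _ in range(30):
            seq = random_dna(rng, int(rng.integers(50, 2000)), gc=0.36)
            got = [(h.left_start, h.spacer_len, h.spacer_seq)
                   for h in scan_pairs(seq, default_query)]
            assert sorted(got) == brute_pairs(seq, default_query)

    def test_strand_symmetry(self, rng):
        q = MotifPairQuery("AAAG", "ACGT", 0, 30)
        q_rc = MotifPairQuery(
            reverse_complement("ACGT"), reverse_complement("AAAG"), 0, 30
        )
        for _ in range(20):
            seq = random_dna(rng, 2000)
            fwd = profile([seq], q).counts
            rev = profile([reverse_complement(seq)], q_rc).counts
            assert fwd == rev

    def test_widening_range_keeps_hits(self, rng):
        seq = random_dna(rng, 3000)
        narrow = scan_pairs(seq, MotifPairQuery("AAAG", "ACGT", 5, 15))
        wide = scan_pairs(seq, MotifPairQuery("AAAG", "ACGT", 0, 30))
        narrow_keys = {(h.left_start, h.spacer_len) for h in narrow}
        wide_keys = {(h.left_start, h.spacer_len) for h in wide}
        assert narrow_keys <= wide_keys

    def test_flanked_motif_implies_core_hit(self, rng):
        """Every TAAAG(N)GACGTC hit implies an AAAG(N+1)ACGT hit: AAAG sits
        one base inside TAAAG and ACGT one base inside GACGTC, so the core
        spacer gains the leading G of GACGTC."""
        flanked = MotifPairQuery("TAAAG", "GACGTC", 0, 28)
        core = MotifPairQuery("AAAG", "ACGT", 0, 30)
        for _ in range(10):
            seq = random_dna(rng, 2000)
            # plant two flanked sites to guarantee hits exist
            for pos, n in ((100, 7), (600, 12)):
                site = "TAAAG" + random_dna(rng, n) + "GACGTC"
                seq = seq[:pos] + site + seq[pos + len(site):]
            core_keys = {(h.left_start, h.spacer_len) for h in scan_pairs(seq, core)}
            for h in scan_pairs(seq, flanked):
                assert (h.left_start + 1, h.spacer_len + 1) in core_keys


class TestProfile:
    def test_counts_across_sequences(self, default_query):
        prof = profile(["AAAGACGT", "AAAGACGT"], default_query)
        assert prof.counts[0] == 2
        assert sum(v for n, v in prof.counts.items() if n != 0) == 0
        assert prof.total_bp == 16
        assert prof.n_sequences == 2

    def test_counts_defined_for_whole_range(self, default_query):
        prof = profile(["AAAGACGT"], default_query)
        assert sorted(prof.counts) == list(range(0, 31))

    def test_published_example_profile(self, default_query):
        prof = profile([SPACER_24_EXAMPLE], default_query)
        assert prof.counts[24] == 1
        assert prof.total_hits() == 1

    def test_hits_do_not_span_sequences(self, default_query):
        # AAAG at end of one sequence, ACGT at start of the next
        prof = profile(["TTTTAAAG", "ACGTTTTT"], default_query)
        assert prof.total_hits() == 0

    def test_matches_bruteforce_on_10kb(self, default_query, rng):
        seq = random_dna(rng, 10_000)
        prof = profile([seq], default_query)
        oracle = brute_pairs(seq, default_query)
        for n in prof.counts:
            assert prof.counts[n] == sum(1 for (_, m, _) in oracle if m == n)

    def test_empty_sequence_set_rejected(self, default_query):
        with pytest.raises(ValueError):
            profile([], default_query)

    def test_both_strands_counts_reverse_orientation(self, default_query):
        seq = reverse_complement("AAAGTTACGT")  # pair only on the minus strand
        assert profile([seq], default_query).total_hits() == 0
        assert profile([seq], default_query, both_strands=True).counts[2] == 1


class TestCollectSpacers:
    def test_spacer_extraction(self, default_query):
        hits = scan_pairs("AAAGTTACGT", default_query)
        assert collect_spacers(hits, 2) == ["TT"]
        assert collect_spacers(hits, 5) == []

    def test_planted_spacers_recovered(self, default_query, rng):
        spacers = [random_dna(rng, 6) for _ in range(5)]
        seqs = ["TT" + "AAAG" + s + "ACGT" + "TT" for s in spacers]
        hits = [h for s in seqs for h in scan_pairs(s, default_query)]
        assert sorted(collect_spacers(hits, 6)) == sorted(spacers)


class TestMotifPairQuery:
    def test_label_autogenerated(self):
        assert MotifPairQuery("AAAG", "ACGT").label == "AAAG(N)ACGT"

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"left_motif": "", "right_motif": "ACGT"},
            {"left_motif": "AAAG", "right_motif": "ACGU"},
            {"left_motif": "AAAG", "right_motif": "ACGT", "min_spacer": 5, "max_spacer": 2},
            {"left_motif": "AAAG", "right_motif": "ACGT", "min_spacer": -1},
        ],
    )
    def test_invalid_queries_rejected(self, kwargs):
        with pytest.raises(Exception):
            MotifPairQuery(**kwargs)
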