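import random

import pytest
from hypothesis import given, settings, strategies as st

from contactscape.pair_filtering import (CandidateLocation, Contact, FilterPolicy,
                                         ReadPairRecord, Rejection,
                                         apply_separation_filter, classify_pair,
                                         filter_pair_stream, read_pair_table,
                                         write_pair_table)

L = CandidateLocation


def rec(end1, end2, read_length=100, read_id="r0"):
    return ReadPairRecord(read_id, tuple(end1), tuple(end2), read_length)


class TestClassifyPair:
    def test_unique_both_ends_accepted(self, genome):
        out = classify_pair(rec([L("chr1", 100_000)], [L("chr1", 105_000)]),
                            FilterPolicy("strict_unique"), genome)
        assert out == Contact("chr1", 100_000, "chr1", 105_000)

    @pytest.mark.parametrize("strategy", ["strict_unique", "four_case"])
    def test_three_candidates_discarded(self, genome, strategy):
        r = rec([L("chr1", 1000), L("chr1", 2000), L("chr2", 3000)], [L("chr1", 9000)])
        assert classify_pair(r, FilterPolicy(strategy), genome) == Rejection("multi_mapped")

    @pytest.mark.parametrize("strategy", ["strict_unique", "four_case"])
    def test_unmapped_end_rejected(self, genome, strategy):
        r = rec([], [L("chr1", 9000)])
        assert classify_pair(r, FilterPolicy(strategy), genome) == Rejection("unmapped")

    def test_strict_rejects_two_candidates(self, genome):
        r = rec([L("chr1", 1000)], [L("chr1", 2000), L("chr2", 3000)])
        assert classify_pair(r, FilterPolicy("strict_unique"), genome) \
            == Rejection("multi_mapped")

    def test_case_two_partner_is_the_distant_candidate(self, genome):
        # the candidate within the insert length of the unique end is the
        # physically linked mate; the other candidate is the contact partner
        r = rec([L("chr2", 50_000)], [L("chr2", 51_000), L("chr5", 900_000)])
        out = classify_pair(r, FilterPolicy("four_case"), genome)
        assert out == Contact("chr2", 50_000, "chr5", 900_000)

    def test_case_two_no_nearby_candidate_invalid(self, genome):
        r = rec([L("chr2", 50_000)], [L("chr2", 990_000), L("chr5", 900_000)])
        assert classify_pair(r, FilterPolicy("four_case"), genome) \
            == Rejection("ambiguous")

    def test_case_three_mirrors_case_two(self, genome):
        r = rec([L("chr2", 51_000), L("chr5", 900_000)], [L("chr2", 50_000)])
        out = classify_pair(r, FilterPolicy("four_case"), genome)
        assert out == Contact("chr2", 50_000, "chr5", 900_000)

    def test_case_four_consistent_candidates_accepted(self, genome):
        r = rec([L("chr1", 100_000), L("chr1", 300_000)],
                [L("chr1", 100_050), L("chr1", 300_040)], read_length=100)
        out = classify_pair(r, FilterPolicy("four_case"), genome)
        assert out == Contact("chr1", 100_000, "chr1", 100_050)

    def test_case_four_inconsistent_rejected(self, genome):
        r = rec([L("chr1", 100_000), L("chr1", 300_000)],
                [L("chr1", 100_150), L("chr1", 300_040)], read_length=100)
        assert classify_pair(r, FilterPolicy("four_case"), genome) \
            == Rejection("ambiguous")

    def test_unknown_chromosome_is_input_error(self, genome):
        with pytest.raises(ValueError, match="unknown chromosome"):
            classify_pair(rec([L("chrX", 100)], [L("chr1", 100)]),
                          FilterPolicy(), genome)

    def test_contacts_emitted_in_canonical_order(self, genome):
        out = classify_pair(rec([L("chr2", 10_000)], [L("chr1", 20_000)]),
                            FilterPolicy(), genome)
        assert out == Contact("chr1", 20_000, "chr2", 10_000)


class TestSeparationFilter:
    @pytest.mark.parametrize("contact,expected", [
        (Contact("chr1", 1000, "chr1", 2999), False),   # separation 1999
        (Contact("chr1", 1000, "chr1", 3000), True),    # boundary: >= 2000 kept
        (Contact("chr1", 1000, "chr2", 1000), True),    # inter always kept
    ])
    def test_boundaries(self, contact, expected):
        assert apply_separation_filter(contact, FilterPolicy()) is expected


class TestFilterStream:
    def records(self):
        return [
            rec([L("chr1", 100_000)], [L("chr1", 105_000)], read_id="a"),
            rec([L("chr1", 9000)], [L("chr2", 9000)], read_id="b"),
            rec([L("chr2", 50_000)], [L("chr2", 500_000)], read_id="c"),
            rec([L("chr1", 1000), L("chr1", 2000), L("chr2", 3)], [L("chr1", 9000)],
                read_id="d"),                                    # multi-mapped
            rec([L("chr1", 1000)], [L("chr1", 2999)], read_id="e"),  # sep 1999
        ]

    def test_counts_and_conservation(self, genome):
        contacts, stats = filter_pair_stream(self.records(), FilterPolicy(), genome)
        assert stats == {"accepted": 3, "multi_mapped": 1, "short_separation": 1}
        assert len(contacts) == 3
        assert sum(stats.values()) == len(self.records())

    def test_empty_input(self, genome):
        contacts, stats = filter_pair_stream([], FilterPolicy(), genome)
        assert contacts == [] and stats == {"accepted": 0}

    def test_duplicates_kept_by_default(self, genome):
        records = [rec([L("chr1", 100_000)], [L("chr1", 105_000)], read_id=f"r{i}")
                   for i in range(4)]
        contacts, stats = filter_pair_stream(records, FilterPolicy(), genome)
        assert len(contacts) == 4

    def test_dedup_flag_collapses_duplicates(self, genome):
        records = [rec([L("chr1", 100_000)], [L("chr1", 105_000)], read_id=f"r{i}")
                   for i in range(4)]
        contacts, stats = filter_pair_stream(records, FilterPolicy(dedup=True), genome)
        assert len(contacts) == 1 and stats["duplicate"] == 3

    def test_order_invariance(self, genome):
        records = self.records()
        shuffled = records[:]
        random.Random(7).shuffle(shuffled)
        c1, _ = filter_pair_stream(records, FilterPolicy(), genome)
        c2, _ = filter_pair_stream(shuffled, FilterPolicy(), genome)
        assert sorted(c1) == sorted(c2)

    def test_refiltering_accepted_contacts_is_identity(self, genome):
        contacts, _ = filter_pair_stream(self.records(), FilterPolicy(), genome)
        again = [rec([L(c.chrom_a, c.pos_a)], [L(c.chrom_b, c.pos_b)], read_id=str(i))
                 for i, c in enumerate(contacts)]
        contacts2, stats2 = filter_pair_stream(again, FilterPolicy(), genome)
        assert contacts2 == contacts
        assert stats2 == {"accepted": len(contacts)}

    def test_strict_accepts_subset_of_four_case(self, genome):
        records = self.records()
        strict, _ = filter_pair_stream(records, FilterPolicy("strict_unique"), genome)
        loose, _ = filter_pair_stream(records, FilterPolicy("four_case"), genome)
        assert set(strict) <= set(loose)


@st.composite
def read_pair_records(draw):
    def location():
        return L(draw(st.sampled_from(["chr1", "chr2"])),
                 draw(st.integers(1, 5_000_000)))
    n1 = draw(st.integers(0, 3))
    n2 = draw(st.integers(0, 3))
    return ReadPairRecord(f"r{draw(st.integers(0, 999))}",
                          tuple(location() for _ in range(n1)),
                          tuple(location() for _ in range(n2)), 100)


@settings(max_examples=60, derandomize=True)
@given(st.lists(read_pair_records(), max_size=25),
       st.sampled_from(["strict_unique", "four_case"]))
def test_every_record_counted_exactly_once(records, strategy):
    from contactscape.genome import Genome
    genome = Genome({"chr1": 5_000_000, "chr2": 5_000_000})
    contacts, stats = filter_pair_stream(records, FilterPolicy(strategy), genome)
    assert sum(stats.values()) == len(records)
    assert stats["accepted"] == len(contacts)
    for c in contacts:
        assert (genome.index(c.chrom_a), c.pos_a) <= (genome.index(c.chrom_b), c.pos_b)
        assert apply_separation_filter(c, FilterPolicy(strategy))


class TestIO:
    def test_round_trip(self, tmp_path, genome):
        records = [
            rec([L("chr1", 10, "+")], [L("chr2", 20, "-")], read_id="a"),
            rec([L("chr1", 10, "+"), L("chr2", 99, "+")], [L("chr1", 5000, "-")],
                read_length=120, read_id="b"),
        ]
        path = tmp_path / "pairs.tsv"
        write_pair_table(records, path)
        assert list(read_pair_table(path)) == records
        # a second write is byte-identical
        path2 = tmp_path / "pairs2.tsv"
        write_pair_table(list(read_pair_table(path)), path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_simple_five_column_dialect(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        path.write_text("x\tchr1\t100\tchr2\t200\n")
        (record,) = read_pair_table(path)
        assert record.end1 == (L("chr1", 100),)
        assert record.end2 == (L("chr2", 200),)

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        path.write_text("ok\tchr1\t100\tchr2\t200\nbroken\tnot-a-number\tx\n")
        with pytest.raises(ValueError, match="line 2"):
            list(read_pair_table(path))
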