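"""Search schemes, approximate matching, deduplication, strands, SAM."""

import random

import pytest

from movedex import apm
from movedex import textcore as tc
from movedex.index import build_index
from movedex.occurrence import Occurrence
from tests.conftest import random_text


def plant_read(rng, body, k, metric, length=None):
    length = length or rng.randint(8, min(24, len(body)))
    p0 = rng.randrange(len(body) - length + 1)
    read = list(body[p0:p0 + length])
    for _ in range(rng.randint(0, k)):
        q = rng.randrange(len(read))
        if metric == "edit" and rng.random() < 0.4:
            if rng.random() < 0.5 and len(read) > 2:
                del read[q]
            else:
                read.insert(q, rng.choice("ACGT"))
        else:
            read[q] = rng.choice("ACGT")
    return "".join(read)


class TestSchemes:
    def test_k0_is_single_exact_search(self):
        scheme = apm.pigeonhole_scheme(0)
        assert scheme.parts == 1
        assert scheme.searches == (apm.Search((0,), (0,), (0,)),)

    def test_k1_matches_known_layout(self):
        scheme = apm.pigeonhole_scheme(1)
        assert set(scheme.searches) == {
            apm.Search((0, 1), (0, 0), (0, 1)),
            apm.Search((1, 0), (0, 0), (0, 1)),
        }

    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_pigeonhole_is_lossless(self, k):
        assert apm.pigeonhole_scheme(k).is_lossless(k)

    def test_anchor_with_error_is_not_covered(self):
        scheme = apm.pigeonhole_scheme(1)
        assert not scheme.searches[0].pi == scheme.searches[1].pi
        # a distribution exceeding k is never covered
        assert not apm.pigeonhole_scheme(1).covers((1, 1))

    def test_disconnected_order_rejected(self):
        with pytest.raises(ValueError, match="connected"):
            apm.Search((0, 2, 1), (0, 0, 0), (0, 1, 1))

    def test_parse_scheme_roundtrip(self):
        text = "0,1 | 0,0 | 0,1\n# comment\n1,0 | 0,0 | 0,1\n"
        scheme = apm.parse_scheme(text)
        assert scheme == apm.pigeonhole_scheme(1)

    def test_direction_switches_bounded_by_parts(self):
        for k in range(4):
            for search in apm.pigeonhole_scheme(k).searches:
                dirs = []
                for t in range(len(search.pi)):
                    if t == 0:
                        left = len(search.pi) == 1 or search.pi[1] > search.pi[0]
                    else:
                        left = search.pi[t] < search.pi[0]
                    dirs.append(left)
                switches = sum(a != b for a, b in zip(dirs, dirs[1:]))
                assert switches <= len(search.pi) - 1


class TestPartition:
    def test_worked_example_split(self):
        assert apm.partition_pattern("TATGTTGGT", 2) == [(0, 5), (5, 9)]

    @pytest.mark.parametrize("length, parts, sizes", [
        (10, 2, [5, 5]),
        (7, 3, [3, 2, 2]),
        (5, 5, [1, 1, 1, 1, 1]),
    ])
    def test_uniform_with_remainder_left(self, length, parts, sizes):
        spans = apm.partition_pattern("A" * length, parts)
        assert [b - a for a, b in spans] == sizes
        assert spans[0][0] == 0 and spans[-1][1] == length

    def test_too_short_pattern_rejected(self):
        with pytest.raises(ValueError):
            apm.partition_pattern("AC", 3)


class TestDedup:
    def test_identical_duplicates_collapse(self):
        a = Occurrence(3, 10, 1, "+", "hamming")
        assert apm.dedup_occurrences([a, a, a]) == {a}

    def test_edit_same_region_keeps_min_distance(self):
        a = Occurrence(3, 10, 2, "+", "edit")
        b = Occurrence(3, 10, 1, "+", "edit")
        c = Occurrence(4, 9, 2, "+", "edit")  # same region, within k
        out = apm.dedup_occurrences([a, b, c], metric="edit", k=2)
        assert out == {b}

    def test_distinct_regions_survive(self):
        a = Occurrence(0, 10, 1, "+", "edit")
        b = Occurrence(50, 10, 1, "+", "edit")
        m = Occurrence(0, 10, 1, "-", "edit")
        out = apm.dedup_occurrences([a, b, m], metric="edit", k=2)
        assert out == {a, b, m}


class TestSearchExecution:
    def test_exact_worked_example(self, example_index):
        occ = apm.run_search_scheme(example_index, "TATGT", 0)
        assert sorted((o.start, o.distance) for o in occ) == [(1, 0), (8, 0)]

    def test_one_mismatch_worked_example(self, example_index, example_text):
        occ = apm.run_search_scheme(example_index, "TATGA", 1, "hamming")
        assert (1, 1) in {(o.start, o.distance) for o in occ}
        assert occ == tc.occurrences_oracle(example_text, "TATGA", 1, "hamming")

    @pytest.mark.parametrize("metric", ["hamming", "edit"])
    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_losslessness_on_random_texts(self, rng, k, metric):
        """The headline property: scheme output equals the exhaustive scan."""
        for _ in range(6):
            t = random_text(rng, 40, 400)
            index = build_index([tc.Text(t.symbols[:-1], name="t")])
            read = plant_read(rng, t.symbols[:-1], k, metric)
            got = apm.run_search_scheme(index, read, k, metric)
            expected = tc.occurrences_oracle(t, read, k, metric)
            assert got == expected, (t.symbols, read, k, metric)

    def test_monotone_in_k(self, rng):
        for _ in range(8):
            t = random_text(rng, 60, 300)
            index = build_index([tc.Text(t.symbols[:-1], name="t")])
            read = plant_read(rng, t.symbols[:-1], 2, "hamming", length=12)
            prev = set()
            for k in range(3):
                occ = {(o.start, o.strand)
                       for o in apm.run_search_scheme(index, read, k, "hamming")}
                assert prev <= occ
                prev = occ


class TestAlignRead:
    def test_reverse_complement_read_maps_to_minus_strand(self, rng):
        t = random_text(rng, 80, 200)
        body = t.symbols[:-1]
        index = build_index([tc.Text(body, name="t")])
        p0 = rng.randrange(len(body) - 20)
        read = tc.reverse_complement(body[p0:p0 + 20])
        hits = apm.align_read(index, read, 0)
        assert any(o.strand == "-" and o.start == p0 for o in hits)

    def test_foreign_symbols_reported_unmapped(self, example_index):
        assert apm.align_read(example_index, "ACGTN", 1) == set()
        assert apm.align_read(example_index, "", 1) == set()

    def test_strand_symmetry(self, rng):
        for _ in range(6):
            t = random_text(rng, 60, 200)
            index = build_index([tc.Text(t.symbols[:-1], name="t")])
            read = plant_read(rng, t.symbols[:-1], 1, "hamming", length=10)
            fwd = apm.align_read(index, read, 1)
            rev = apm.align_read(index, tc.reverse_complement(read), 1)
            flip = {"+": "-", "-": "+"}
            assert {(o.start, flip[o.strand], o.distance) for o in fwd} == \
                   {(o.start, o.strand, o.distance) for o in rev}

    def test_fragment_boundary_hits_discarded(self):
        # the read exists only across the junction of the two fragments
        index = build_index([tc.Text("AAAACCCC", name="f1"),
                             tc.Text("GGGGTTTT", name="f2")])
        hits = apm.align_read(index, "CCCCGGGG", 0)
        assert all(o.strand == "-" or o.start + o.length <= 8 or o.start >= 8
                   for o in hits)
        assert not any(o.start < 8 < o.start + o.length for o in hits)

    def test_unmapped_read_absent_from_text(self, example_index):
        assert apm.align_read(example_index, "AAAAAAAAAA", 0) == set()


class TestSAM:
    def test_unmapped_line(self, example_index):
        lines = apm.sam_lines("r1", "ACGT", set(), example_index)
        assert lines == ["r1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*"]

    def test_mapped_lines_have_position_and_nm(self, example_index):
        occ = apm.run_search_scheme(example_index, "TATGT", 0)
        lines = apm.sam_lines("r1", "TATGT", occ, example_index)
        assert len(lines) == 2
        fields = lines[0].split("\t")
        assert fields[1] == "0" and fields[2] == "toy"
        assert fields[3] == "2"  # start 1, SAM is 1-based
        assert fields[5] == "*"  # no CIGAR support
        assert "NM:i:0" in lines[0]

    def test_header_lists_fragments(self, example_index):
        header = apm.sam_header(example_index.fragments)
        assert header[0].startswith("@HD")
        assert any("SN:toy" in line and "LN:18" in line for line in header)
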