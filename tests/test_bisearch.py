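"""Bidirectional extensions: walks, synchronization, toeholds, switches."""

import random

import pytest

from movedex import bisearch as bi
from movedex import movetables as mt
from movedex import textcore as tc
from movedex.index import build_index
from tests.conftest import random_text


def make_searcher(text: tc.Text):
    ss = tc.build_suffix_structures(text)
    ssr = tc.build_suffix_structures(tc.reverse_text(text))
    mlf = mt.build_lf_table(ss)
    mlfrev = mt.build_lf_table(ssr, "lfrev")
    searcher = bi.BiSearcher(
        mlf, mlfrev,
        bi.SASamples.from_structures(ss, mlf),
        bi.SASamples.from_structures(ssr, mlfrev),
        ss.n,
    )
    return searcher, ss


def add_char_left_naive(searcher, state, c):
    """|Sigma|-pass reference: x as the summed widths of the a-extensions."""
    t = searcher.mlf
    nxt = bi.walk_to_next_run(t, state.s, state.Rs, state.e, c)
    if nxt == bi.NOT_FOUND:
        return None
    x = 0
    for a in "$ACGT":
        if not mt.char_precedes(a, c):
            continue
        sub = bi.add_char(t, state.s, state.e, state.Rs, state.Re, a)
        if sub is not None:
            x += sub[1] - sub[0] + 1
    fast = searcher.add_char_left(state, c)
    # the memoized path must produce the identical reverse interval
    assert fast.srev == state.srev + x
    return fast


class TestWalks:
    def test_walk_to_next_run_worked_example(self, example_ss):
        lf = mt.build_lf_table(example_ss)
        assert bi.walk_to_next_run(lf, 0, 0, 18, "A") == (12, 7)

    def test_walk_from_inside_matching_run(self, example_ss):
        lf = mt.build_lf_table(example_ss)
        assert bi.walk_to_next_run(lf, 3, 1, 18, "T") == (3, 1)

    def test_walk_not_found_in_narrow_interval(self, example_ss):
        lf = mt.build_lf_table(example_ss)  # interval [6,6] is the '$' run
        assert bi.walk_to_next_run(lf, 6, 2, 6, "A") == bi.NOT_FOUND

    def test_walk_to_previous_run_worked_example(self, example_ss):
        lf = mt.build_lf_table(example_ss)
        assert bi.walk_to_previous_run(lf, 18, 11, "A") == (17, 10)

    def test_walk_to_previous_from_matching_run(self, example_ss):
        lf = mt.build_lf_table(example_ss)
        assert bi.walk_to_previous_run(lf, 17, 10, "A") == (17, 10)

    def test_walks_agree_with_bwt_scan(self, rng):
        for _ in range(40):
            ss = tc.build_suffix_structures(random_text(rng, 2, 150))
            lf = mt.build_lf_table(ss)
            n = ss.n
            s = rng.randrange(n)
            e = rng.randrange(s, n)
            Rs = mt.find_row(lf, s, 0, lf.nrows - 2)
            Re = mt.find_row(lf, e, 0, lf.nrows - 2)
            c = rng.choice("ACGT")
            hits = [i for i in range(s, e + 1) if ss.bwt[i] == c]
            got = bi.walk_to_next_run(lf, s, Rs, e, c)
            if not hits:
                assert got == bi.NOT_FOUND
            else:
                assert got[0] == hits[0]
                ec, _ = bi.walk_to_previous_run(lf, e, Re, c)
                assert ec == hits[-1]


class TestAddChar:
    def test_full_interval_extension_t(self, example_ss):
        lf = mt.build_lf_table(example_ss)
        s2, e2, *_ = bi.add_char(lf, 0, 18, 0, 11, "T")
        assert (s2, e2) == (11, 18)

    def test_absent_char_returns_none(self, example_ss):
        lf = mt.build_lf_table(example_ss)
        assert bi.add_char(lf, 6, 6, 2, 2, "A") is None

    def test_interval_width_equals_char_count(self, rng):
        for _ in range(30):
            ss = tc.build_suffix_structures(random_text(rng, 2, 150))
            lf = mt.build_lf_table(ss)
            c = rng.choice("ACGT")
            res = bi.add_char(lf, 0, ss.n - 1, 0, lf.nrows - 2, c)
            count = ss.bwt.count(c)
            if count == 0:
                assert res is None
            else:
                assert res[1] - res[0] + 1 == count


class TestBidirectional:
    def test_five_left_extensions_reach_printed_state(self, example_text):
        searcher, _ = make_searcher(example_text)
        state = searcher.initial_state()
        for c in reversed("TATGT"):
            state = searcher.add_char_left(state, c)
        assert (state.s, state.e, state.Rs, state.Re) == (11, 12, 6, 7)
        assert (state.srev, state.erev) == (16, 17)
        assert (state.Rsrev, state.Rerev) == (0, 12)  # stale, kept as bracket

    def test_switch_recovers_reverse_run_indices(self, example_text):
        searcher, _ = make_searcher(example_text)
        state = searcher.initial_state()
        for c in reversed("TATGT"):
            state = searcher.add_char_left(state, c)
        switched = searcher.switch_direction(state, "reverse")
        assert (switched.Rsrev, switched.Rerev) == (10, 11)
        assert searcher.switch_direction(switched, "reverse") == switched

    def test_update_run_indices_printed_values(self, example_ss_rev):
        mlfrev = mt.build_lf_table(example_ss_rev, "lfrev")
        assert bi.update_run_indices(mlfrev, 16, 0, 12) == 10
        assert bi.update_run_indices(mlfrev, 17, 0, 12) == 11
        assert bi.update_run_indices(mlfrev, mlfrev.row_p(3), 3, 9) == 3

    def test_right_extension_after_switch_narrows_to_one(self, example_text):
        searcher, _ = make_searcher(example_text)
        state = searcher.initial_state()
        for c in reversed("TATGT"):
            state = searcher.add_char_left(state, c)
        state = searcher.switch_direction(state, "reverse")
        state = searcher.add_char_right(state, "T")
        assert state.width == 1  # "TATGTT" occurs once in the example text
        assert example_text.symbols[state.toehold:state.toehold + 6] == "TATGTT"

    def test_stale_side_extension_rejected(self, example_text):
        searcher, _ = make_searcher(example_text)
        state = searcher.initial_state()
        state = searcher.add_char_left(state, "T")
        with pytest.raises(mt.MoveContractError):
            searcher.add_char_right(state, "T")

    def test_memoized_matches_naive_reference(self, rng):
        for _ in range(30):
            text = random_text(rng, 4, 120)
            searcher, _ = make_searcher(text)
            state = searcher.initial_state()
            for _ in range(6):
                c = rng.choice("ACGT")
                nxt = add_char_left_naive(searcher, state, c)
                if nxt is None:
                    break
                state = nxt

    def test_random_interleavings_match_interval_oracle(self, rng):
        """Exact-match completeness, synchronization and toehold invariants
        over randomized left/right extension sequences with switches."""
        for _ in range(60):
            text = random_text(rng, 2, 250)
            searcher, ss = make_searcher(text)
            state = searcher.initial_state()
            pattern = ""
            for _ in range(rng.randint(1, 14)):
                c = rng.choice("ACGT")
                if rng.random() < 0.5:
                    state_f = searcher.switch_direction(state, "forward")
                    nxt = searcher.add_char_left(state_f, c)
                    cand = c + pattern
                    base = state_f
                else:
                    state_r = searcher.switch_direction(state, "reverse")
                    nxt = searcher.add_char_right(state_r, c)
                    cand = pattern + c
                    base = state_r
                lo, hi = tc.interval_oracle(ss, cand)
                if nxt is None:
                    assert lo > hi
                    state = base
                    continue
                pattern, state = cand, nxt
                assert (state.s, state.e) == (lo, hi)
                assert state.e - state.s == state.erev - state.srev
                assert text.symbols[state.toehold:state.toehold + state.m] \
                    == pattern
                # the fresh side's run indices really contain the boundaries
                table = searcher.mlf if state.fwd_fresh else searcher.mlfrev
                s_, e_ = ((state.s, state.e) if state.fwd_fresh
                          else (state.srev, state.erev))
                Rs_, Re_ = ((state.Rs, state.Re) if state.fwd_fresh
                            else (state.Rsrev, state.Rerev))
                assert table.row_p(Rs_) <= s_ < table.row_p(Rs_ + 1)
                assert table.row_p(Re_) <= e_ < table.row_p(Re_ + 1)

    def test_left_then_right_equals_right_then_left(self, rng):
        for _ in range(20):
            text = random_text(rng, 20, 150)
            searcher, ss = make_searcher(text)
            body = text.symbols[:-1]
            p0 = rng.randrange(max(1, len(body) - 6))
            q = body[p0:p0 + rng.randint(2, 6)]
            mid = len(q) // 2

            def run(order):
                st = searcher.initial_state()
                for side, ch in order:
                    st = searcher.switch_direction(
                        st, "forward" if side == "L" else "reverse")
                    st = (searcher.add_char_left(st, ch) if side == "L"
                          else searcher.add_char_right(st, ch))
                    assert st is not None
                return st

            lefts = [("L", c) for c in reversed(q[:mid])]
            rights = [("R", c) for c in q[mid:]]
            a = run(rights + lefts)
            b = run(lefts + rights)
            assert (a.s, a.e, a.srev, a.erev) == (b.s, b.e, b.srev, b.erev)

    def test_single_run_interval_decrements_toehold(self, rng):
        """Left extensions from an interval inside one BWT run must shift the
        tracked occurrence by exactly one position."""
        seen = 0
        for _ in range(200):
            text = random_text(rng, 5, 60)
            searcher, _ = make_searcher(text)
            state = searcher.initial_state()
            for _ in range(8):
                c = rng.choice("ACGT")
                single_run = state.Rs == state.Re
                nxt = searcher.add_char_left(state, c)
                if nxt is None:
                    break
                if single_run:
                    seen += 1
                    assert nxt.toehold == state.toehold - 1
                state = nxt
        assert seen > 0  # the scenario actually occurred
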