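"""Synchronized bidirectional character extensions over two LF move tables.

A pattern under construction is represented by a :class:`BiState`: the closed
SA interval [s, e] of the pattern in the forward text, the interval
[srev, erev] of the reversed pattern in the reversed text, the run indices
bracketing both intervals, the matched length, and a *toehold* — the text
start of one concrete occurrence, maintained through every extension so that
locating can start without any stored suffix array.

Left extensions update the forward interval via the move table and
resynchronize the reverse interval arithmetically: with x the number of BWT
characters smaller than c inside [s, e] and y the new interval width,
srev' = srev + x and erev' = srev + x + y - 1. Right extensions mirror this
on the reverse table. Only the active side's run indices are kept fresh; the
stale side is recovered by binary search when the search direction switches.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .movetables import (
    MoveContractError,
    MoveTable,
    StepStats,
    char_precedes,
    find_row,
    move_step,
)
from .textcore import SuffixStructures

NOT_FOUND = (-1, -1)


@dataclass(frozen=True)
class BiState:
    s: int
    e: int
    Rs: int
    Re: int
    srev: int
    erev: int
    Rsrev: int
    Rerev: int
    m: int = 0
    toehold: int = 0
    fwd_fresh: bool = True
    rev_fresh: bool = True

    @property
    def width(self) -> int:
        return self.e - self.s + 1


@dataclass
class SASamples:
    """Per-run SA samples: the SA value at each run's first and last position."""

    start_sa: list[int]
    end_sa: list[int]

    @classmethod
    def from_structures(cls, ss: SuffixStructures, table: MoveTable) -> "SASamples":
        start_sa, end_sa = [], []
        for j in range(table.nrows - 1):
            start_sa.append(int(ss.sa[table.row_p(j)]))
            end_sa.append(int(ss.sa[table.row_p(j + 1) - 1]))
        return cls(start_sa, end_sa)


# ---------------------------------------------------------------------------
# single-table primitives


def walk_to_next_run(table, s, Rs, e, c, stats: StepStats | None = None):
    """Smallest position sc in [s, e] inside a run of c, with its run index.

    Returns ``NOT_FOUND`` when c does not occur in BWT[s..e].
    """
    j, sc = Rs, s
    steps = 0
    while j < table.nrows - 1 and table.row_char(j) != c:
        j += 1
        sc = table.row_p(j)
        steps += 1
    if stats is not None:
        stats.record(steps)
    if j >= table.nrows - 1 or sc > e:
        return NOT_FOUND
    return sc, j


def walk_to_previous_run(table, e, Re, c, stats: StepStats | None = None):
    """Largest position ec <= e inside a run of c, with its run index.

    Contract: c is known to occur at or before e (a prior walk_to_next_run
    guarantees this); run ends are read from the following row's p.
    """
    j, ec = Re, e
    steps = 0
    while j >= 0 and table.row_char(j) != c:
        j -= 1
        ec = table.row_p(j + 1) - 1
        steps += 1
    if stats is not None:
        stats.record(steps)
    if j < 0:
        raise MoveContractError(f"no run of {c!r} at or before position {e}")
    return ec, j


def add_char(table, s, e, Rs, Re, c, stats: StepStats | None = None):
    """Backward step: interval of cP from the interval [s, e] of P, or None."""
    nxt = walk_to_next_run(table, s, Rs, e, c, stats)
    if nxt == NOT_FOUND:
        return None
    sc, Rsc = nxt
    ec, Rec = walk_to_previous_run(table, e, Re, c, stats)
    s2, Rs2 = move_step(table, sc, Rsc)
    e2, Re2 = move_step(table, ec, Rec)
    return s2, e2, Rs2, Re2


def update_run_indices(table, i, lo, hi):
    """Binary-search recovery of the run containing i within rows [lo, hi]."""
    return find_row(table, i, lo, hi)


def count_smaller(table, s, e, Rs, Re, c) -> int:
    """|{k in [s, e] : BWT[k] < c}| by one walk over the covering runs.

    The sentinel counts too: '$' precedes every alphabet character.
    """
    x = 0
    for j in range(Rs, Re + 1):
        if char_precedes(table.row_char(j), c):
            lo = max(s, table.row_p(j))
            hi = min(e, table.row_p(j + 1) - 1)
            x += hi - lo + 1
    return x


# ---------------------------------------------------------------------------
# the bidirectional searcher


class BiSearcher:
    """Bidirectional extension engine over a forward and a reverse LF table."""

    def __init__(self, mlf: MoveTable, mlfrev: MoveTable,
                 samples_fwd: SASamples, samples_rev: SASamples, n: int):
        self.mlf = mlf
        self.mlfrev = mlfrev
        self.samples_fwd = samples_fwd
        self.samples_rev = samples_rev
        self.n = n
        self.walk_stats = StepStats()

    def initial_state(self) -> BiState:
        """The empty-pattern state: full intervals on both sides."""
        n = self.n
        return BiState(
            s=0, e=n - 1, Rs=0, Re=self.mlf.nrows - 2,
            srev=0, erev=n - 1, Rsrev=0, Rerev=self.mlfrev.nrows - 2,
            m=0, toehold=self.samples_fwd.end_sa[-1],
            fwd_fresh=True, rev_fresh=True,
        )

    # -- extensions ---------------------------------------------------------

    def add_char_left(self, state: BiState, c: str) -> BiState | None:
        """Extend P to cP; returns None when c cannot extend the match."""
        if not state.fwd_fresh:
            raise MoveContractError("forward run indices are stale; switch first")
        t = self.mlf
        nxt = walk_to_next_run(t, state.s, state.Rs, state.e, c, self.walk_stats)
        if nxt == NOT_FOUND:
            return None
        sc, Rsc = nxt
        ec, Rec = walk_to_previous_run(t, state.e, state.Re, c, self.walk_stats)
        x = count_smaller(t, state.s, state.e, state.Rs, state.Re, c)
        s2, Rs2 = move_step(t, sc, Rsc)
        e2, Re2 = move_step(t, ec, Rec)
        y = e2 - s2 + 1
        toehold = self._toehold_left(state, sc, Rsc, ec, Rec)
        return replace(
            state,
            s=s2, e=e2, Rs=Rs2, Re=Re2,
            srev=state.srev + x, erev=state.srev + x + y - 1,
            m=state.m + 1, toehold=toehold,
            fwd_fresh=True, rev_fresh=False,
        )

    def add_char_right(self, state: BiState, c: str) -> BiState | None:
        """Extend P to Pc; the mirror of :meth:`add_char_left`."""
        if not state.rev_fresh:
            raise MoveContractError("reverse run indices are stale; switch first")
        t = self.mlfrev
        nxt = walk_to_next_run(t, state.srev, state.Rsrev, state.erev, c,
                               self.walk_stats)
        if nxt == NOT_FOUND:
            return None
        sc, Rsc = nxt
        ec, Rec = walk_to_previous_run(t, state.erev, state.Rerev, c,
                                       self.walk_stats)
        x = count_smaller(t, state.srev, state.erev, state.Rsrev, state.Rerev, c)
        s2, Rs2 = move_step(t, sc, Rsc)
        e2, Re2 = move_step(t, ec, Rec)
        y = e2 - s2 + 1
        toehold = self._toehold_right(state, sc, Rsc, ec, Rec)
        return replace(
            state,
            srev=s2, erev=e2, Rsrev=Rs2, Rerev=Re2,
            s=state.s + x, e=state.s + x + y - 1,
            m=state.m + 1, toehold=toehold,
            fwd_fresh=False, rev_fresh=True,
        )

    # -- toehold maintenance ------------------------------------------------

    def _boundary_sample(self, state_s, state_e, Rs, Re, sc, Rsc, ec, Rec,
                         samples: SASamples):
        """SA sample of a c-run boundary inside the interval, or None when the
        whole interval [s, e] lies within a single run (of c)."""
        if Rs == Re:
            return None
        if Rsc != Rec:
            return samples.end_sa[Rsc]
        if sc > state_s:
            return samples.start_sa[Rsc]
        if ec < state_e:
            return samples.end_sa[Rec]
        raise AssertionError("unreachable: multi-run interval with no c boundary")

    def _toehold_left(self, state, sc, Rsc, ec, Rec) -> int:
        sample = self._boundary_sample(
            state.s, state.e, state.Rs, state.Re, sc, Rsc, ec, Rec,
            self.samples_fwd,
        )
        if sample is None:
            # every position in [s, e] carries c: the old occurrence extends
            return state.toehold - 1
        return sample - 1

    def _toehold_right(self, state, sc, Rsc, ec, Rec) -> int:
        sample = self._boundary_sample(
            state.srev, state.erev, state.Rsrev, state.Rerev, sc, Rsc, ec, Rec,
            self.samples_rev,
        )
        if sample is None:
            # all occurrences of P continue with c; the start is unchanged
            return state.toehold
        # map the reverse-text occurrence start back to forward coordinates
        jrev = sample - 1
        return self.n - 1 - jrev - (state.m + 1)

    # -- direction switches -------------------------------------------------

    def switch_direction(self, state: BiState, to: str) -> BiState:
        """Refresh one side's run indices (binary search from the last-known
        bracketing rows); idempotent when that side is already fresh."""
        if to == "forward":
            if state.fwd_fresh:
                return state
            Rs = update_run_indices(self.mlf, state.s, state.Rs, state.Re)
            Re = update_run_indices(self.mlf, state.e, Rs, state.Re)
            return replace(state, Rs=Rs, Re=Re, fwd_fresh=True)
        if to == "reverse":
            if state.rev_fresh:
                return state
            Rs = update_run_indices(self.mlfrev, state.srev, state.Rsrev,
                                    state.Rerev)
            Re = update_run_indices(self.mlfrev, state.erev, Rs, state.Rerev)
            return replace(state, Rsrev=Rs, Rerev=Re, rev_fresh=True)
        raise ValueError(f"unknown direction {to!r}")
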