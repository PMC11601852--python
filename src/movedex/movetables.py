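"""Run-length move tables: construction, balancing, and the move-step primitive.

A move table represents a permutation of [0, n) (LF for the forward or
reverse BWT, or phi / inverse phi over text positions) as a short list of
rows, one per *input interval* on which the permutation is a simple shift.
Each row stores the interval start ``p``, the mapped start ``pi`` of its
*output interval*, and the row index ``xi`` whose input interval contains
``pi``. Evaluating the permutation is then a constant-size table jump plus a
short linear "fast forward" over subsequent rows, which is the cache-friendly
replacement for the rank/select machinery of run-length FM-indexes.

LF tables keep one row per maximal BWT run (plus a sentinel row with p = n);
they are deliberately left unbalanced. The phi tables' run-size distribution
is heavily right-tailed, so those are balanced: input intervals are split
until no output interval spans more than ``d`` input-interval starts, which
caps fast-forward work without changing the mapping and at most doubles the
row count.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

from .textcore import (
    CODE,
    SuffixStructures,
    lf_oracle,
    phi_inv_oracle,
    phi_oracle,
)


class MoveContractError(RuntimeError):
    """An operation was called with a row that does not contain its position."""


@dataclass(frozen=True)
class MoveRow:
    c: str | None
    p: int
    pi: int
    xi: int


@dataclass
class StepStats:
    """Fast-forward / walk instrumentation, kept as a step-count histogram."""

    calls: int = 0
    steps: int = 0
    histogram: dict[int, int] = field(default_factory=dict)

    def record(self, k: int) -> None:
        self.calls += 1
        self.steps += k
        self.histogram[k] = self.histogram.get(k, 0) + 1

    @property
    def mean(self) -> float:
        return self.steps / self.calls if self.calls else 0.0


class MoveTable:
    """In-memory ("full") move table. Rows include the final sentinel row.

    The rows partition [0, n): row j's input interval is
    [p[j], p[j+1] - 1], and the sentinel row has p = pi = n so boundary
    accesses in fast forwarding never run off the end.
    """

    def __init__(self, kind, n, p, pi, xi, chars=None, balanced=False):
        self.kind = kind
        self.n = int(n)
        self._p = [int(v) for v in p]
        self._pi = [int(v) for v in pi]
        self._xi = [int(v) for v in xi]
        self._chars = list(chars) if chars is not None else None
        self.balanced = balanced
        self.ff_stats = StepStats()
        self._validate()

    # -- row access protocol (shared with PackedTable) ----------------------
    @property
    def nrows(self) -> int:
        return len(self._p)

    @property
    def has_chars(self) -> bool:
        return self._chars is not None

    def row_p(self, j: int) -> int:
        return self._p[j]

    def row_pi(self, j: int) -> int:
        return self._pi[j]

    def row_xi(self, j: int) -> int:
        return self._xi[j]

    def row_char(self, j: int) -> str | None:
        return self._chars[j] if self._chars is not None else None

    def row(self, j: int) -> MoveRow:
        return MoveRow(self.row_char(j), self._p[j], self._pi[j], self._xi[j])

    def rows(self):
        return [self.row(j) for j in range(self.nrows)]

    def _validate(self) -> None:
        if self._p[0] != 0 or self._p[-1] != self.n or self._pi[-1] != self.n:
            raise ValueError("move table must span [0, n] with a sentinel row")
        if any(a >= b for a, b in zip(self._p, self._p[1:])):
            raise ValueError("input-interval starts must be strictly increasing")
        if self._chars is not None and len(self._chars) != len(self._p):
            raise ValueError("char column length mismatch")


# ---------------------------------------------------------------------------
# construction


def compute_runs(bwt: str) -> list[tuple[str, int]]:
    """Maximal equal-character runs of the BWT as (char, start) pairs."""
    if not bwt:
        raise ValueError("empty BWT")
    runs = [(bwt[0], 0)]
    for i in range(1, len(bwt)):
        if bwt[i] != bwt[i - 1]:
            runs.append((bwt[i], i))
    return runs


def _containing_rows(p: list[int], targets: list[int]) -> list[int]:
    return [bisect_right(p, t) - 1 for t in targets]


def build_lf_table(ss: SuffixStructures, kind: str = "lf") -> MoveTable:
    """One row per BWT run: (c, p, pi=LF(p), xi = row containing pi)."""
    runs = compute_runs(ss.bwt)
    n = ss.n
    p = [start for _, start in runs]
    pi = [lf_oracle(ss, start) for start in p]
    chars = [c for c, _ in runs]
    # sentinel row: p = pi = n, xi = its own index (as printed in the tables)
    p.append(n)
    pi.append(n)
    chars.append("")
    xi = _containing_rows(p[:-1], pi[:-1]) + [len(p) - 1]
    return MoveTable(kind, n, p, pi, xi, chars=chars)


def build_phi_tables(ss: SuffixStructures) -> tuple[MoveTable, MoveTable]:
    """Unbalanced phi and inverse-phi move tables.

    A phi input interval begins at text position k exactly when k = SA[i]
    for a BWT-run start i; inverse phi's input intervals begin at SA values
    of run ends. Every row is validated against the direct SA/ISA oracle.
    """
    runs = compute_runs(ss.bwt)
    n = ss.n
    run_starts = [start for _, start in runs]
    run_ends = [start - 1 for _, start in runs[1:]] + [n - 1]

    phi_p = sorted(int(ss.sa[i]) for i in run_starts)
    phi_pi = [phi_oracle(ss, k) for k in phi_p]
    inv_p = sorted(int(ss.sa[i]) for i in run_ends)
    inv_pi = [phi_inv_oracle(ss, k) for k in inv_p]

    tables = []
    for kind, p, pi in (("phi", phi_p, phi_pi), ("phiinv", inv_p, inv_pi)):
        p = p + [n]
        pi = pi + [n]
        xi = _containing_rows(p[:-1], pi[:-1]) + [len(p) - 1]
        table = MoveTable(kind, n, p, pi, xi)
        _check_shift_consistency(ss, table)
        tables.append(table)
    return tables[0], tables[1]


def _check_shift_consistency(ss: SuffixStructures, table: MoveTable) -> None:
    """Each input interval must map as one shift (consecutiveness property)."""
    oracle = phi_oracle if table.kind == "phi" else phi_inv_oracle
    for j in range(table.nrows - 1):
        p, pi, end = table.row_p(j), table.row_pi(j), table.row_p(j + 1)
        if oracle(ss, p) != pi or oracle(ss, end - 1) != pi + (end - 1 - p):
            raise AssertionError(
                f"{table.kind} row {j} is not a consecutive shift"
            )


# ---------------------------------------------------------------------------
# balancing


def balance(table: MoveTable, d: int = 2) -> MoveTable:
    """Split input intervals until no output interval fully contains more
    than ``d`` input-interval start points.

    Splits happen at the (d+1)-th contained start, splitting the input and
    output interval alike, so the represented mapping is unchanged. Rows are
    processed left to right, re-scanning after each split, until a fixpoint;
    the result has at most twice the original number of rows.
    """
    if d < 2:
        raise ValueError("balancing parameter d must be >= 2")
    n = table.n
    p = [table.row_p(j) for j in range(table.nrows - 1)]
    pi = [table.row_pi(j) for j in range(table.nrows - 1)]
    chars = (
        [table.row_char(j) for j in range(table.nrows - 1)]
        if table.has_chars
        else None
    )
    original_rows = len(p)

    restart = True
    while restart:
        restart = False
        for j in range(len(p)):
            width = (p[j + 1] if j + 1 < len(p) else n) - p[j]
            out_lo = pi[j]
            out_hi = out_lo + width - 1
            a = bisect_left(p, out_lo)
            b = bisect_right(p, out_hi)
            if b - a > d:
                split = p[a + d] - out_lo  # offset of the (d+1)-th start
                p.insert(j + 1, p[j] + split)
                pi.insert(j + 1, pi[j] + split)
                if chars is not None:
                    chars.insert(j + 1, chars[j])
                restart = True
                break

    assert len(p) <= 2 * original_rows
    p.append(n)
    pi.append(n)
    if chars is not None:
        chars.append("")
    xi = _containing_rows(p[:-1], pi[:-1]) + [len(p) - 1]
    return MoveTable(table.kind, n, p, pi, xi, chars=chars, balanced=True)


# ---------------------------------------------------------------------------
# evaluation primitives


def fast_forward(table, i: int, j: int) -> tuple[int, int]:
    """Smallest row j' >= j whose input interval contains i, plus step count."""
    if i >= table.n:
        raise IndexError(f"position {i} out of domain [0, {table.n})")
    if table.row_p(j) > i:
        raise MoveContractError(f"fast_forward start row {j} lies beyond {i}")
    steps = 0
    while table.row_p(j + 1) <= i:
        j += 1
        steps += 1
    return j, steps


def move_step(table, i: int, j: int) -> tuple[int, int]:
    """Map position i through row j's shift; return (mapped, containing row).

    ``j`` must be the row whose input interval contains ``i`` — the input
    side is never silently fast-forwarded.
    """
    pj = table.row_p(j)
    if not (pj <= i < table.row_p(j + 1)):
        raise MoveContractError(
            f"move_step: row {j} ([{pj}, {table.row_p(j + 1)})) does not contain {i}"
        )
    mapped = table.row_pi(j) + (i - pj)
    row, steps = fast_forward(table, mapped, table.row_xi(j))
    stats = getattr(table, "ff_stats", None)
    if stats is not None:
        stats.record(steps)
    return mapped, row


def find_row(table, i: int, lo: int, hi: int) -> int:
    """Binary search for the row containing i, restricted to rows [lo, hi]."""
    if not (table.row_p(lo) <= i < table.row_p(hi + 1)):
        raise MoveContractError(
            f"find_row: position {i} outside rows [{lo}, {hi}]"
        )
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if table.row_p(mid) <= i:
            lo = mid
        else:
            hi = mid - 1
    return lo


def char_precedes(a: str, b: str) -> bool:
    """Symbol order with the sentinel smallest: $ < A < C < G < T."""
    return CODE[a] < CODE[b]
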