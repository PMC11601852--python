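"""From one toehold to all occurrences: phi walks with the PLCP stop rule.

A finished search state carries one concrete occurrence start (the toehold)
somewhere inside its SA interval [s, e]. The remaining starts are the SA
values of the neighbouring interval entries, reached by iterating phi
(previous SA value) and inverse phi (next SA value). The interval boundary
is detected with the permuted LCP array: for a pattern of length m matched
by interval [s, e], PLCP is >= m at SA[i] for s < i <= e and drops below m
at SA[s] and SA[e+1]. The walk backward stops on that drop; the forward walk
then performs exactly the arithmetic remainder of steps, so a width-w
interval costs exactly w - 1 phi / inverse-phi operations in total.

PLCP itself is stored sparsely: its value at every phi input-interval start
(these are exactly the irreducible PLCP positions), recovered elsewhere by
PLCP[i] = PLCP[pred(i)] - (i - pred(i)).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import numpy as np

from .bisearch import BiState
from .movetables import MoveTable, find_row, move_step
from .occurrence import Occurrence  # noqa: F401  (re-exported; created here)
from .textcore import SuffixStructures, phi_inv_oracle, phi_oracle

#: indexes at most this long get a full PLCP verification at build time
VERIFY_LIMIT = 1 << 17


class LocateError(RuntimeError):
    """Internal consistency failure while enumerating an interval."""


@dataclass
class PLCPSamples:
    """PLCP values sampled at the phi input-interval starts (sorted)."""

    positions: list[int]
    values: list[int]

    @classmethod
    def from_structures(cls, ss: SuffixStructures,
                        sample_positions: list[int]) -> "PLCPSamples":
        values = [int(ss.lcp[ss.isa[p]]) for p in sample_positions]
        samples = cls(list(sample_positions), values)
        if ss.n <= VERIFY_LIMIT:
            samples.verify(ss)
        return samples

    def plcp(self, i: int) -> int:
        """Predecessor lookup plus the decrement-by-offset recovery rule."""
        idx = bisect_right(self.positions, i) - 1
        if idx < 0:
            raise IndexError(f"position {i} precedes every PLCP sample")
        p = self.positions[idx]
        return self.values[idx] - (i - p)

    def verify(self, ss: SuffixStructures) -> None:
        """Cross-check recovery against the LCP-derived PLCP for every position."""
        plcp_full = np.asarray(ss.lcp)[ss.isa]
        for i in range(ss.n):
            if self.plcp(i) != int(plcp_full[i]):
                raise AssertionError(f"PLCP recovery mismatch at position {i}")


class Locator:
    """Enumerates all occurrence starts of a finished search state.

    Runs either on balanced phi / inverse-phi move tables (the default) or,
    when the index was built without them, on retained suffix structures
    (`locate_all_no_tables`), trading memory for locate speed.
    """

    def __init__(self, plcp: PLCPSamples, n: int,
                 mphi: MoveTable | None = None,
                 mphiinv: MoveTable | None = None,
                 fallback: SuffixStructures | None = None):
        self.plcp = plcp
        self.n = n
        self.mphi = mphi
        self.mphiinv = mphiinv
        self.fallback = fallback
        self.op_count = 0

    @property
    def has_tables(self) -> bool:
        return self.mphi is not None and self.mphiinv is not None

    # -- single phi steps ---------------------------------------------------

    def phi_move(self, i: int, row: int | None = None) -> tuple[int, int]:
        """phi(i) via the move table; carries (position, row) pairs."""
        if row is None:
            row = find_row(self.mphi, i, 0, self.mphi.nrows - 2)
        self.op_count += 1
        return move_step(self.mphi, i, row)

    def phi_inv_move(self, i: int, row: int | None = None) -> tuple[int, int]:
        if row is None:
            row = find_row(self.mphiinv, i, 0, self.mphiinv.nrows - 2)
        self.op_count += 1
        return move_step(self.mphiinv, i, row)

    # -- interval enumeration -----------------------------------------------

    def locate_all(self, state: BiState) -> list[int]:
        """All occurrence starts {SA[i] : i in [s, e]} of a non-empty state."""
        if not self.has_tables:
            raise LocateError(
                "index was built without phi move tables; "
                "use locate_all_no_tables"
            )
        return self._walk(state, self.phi_move, self.phi_inv_move)

    def locate_all_no_tables(self, state: BiState) -> list[int]:
        """Same contract as locate_all, via the retained sparse fallback."""
        if self.fallback is None:
            raise LocateError("no fallback suffix structures were retained")

        def phi(i, row=None):
            self.op_count += 1
            return phi_oracle(self.fallback, i), None

        def phi_inv(i, row=None):
            self.op_count += 1
            return phi_inv_oracle(self.fallback, i), None

        return self._walk(state, phi, phi_inv)

    def _walk(self, state: BiState, phi, phi_inv) -> list[int]:
        m, width = state.m, state.width
        if width <= 0:
            raise LocateError("cannot locate an empty state")
        starts = [state.toehold]
        if width == 1:
            return starts
        # backward: each step yields the previous SA value; the entry whose
        # PLCP drops below m is SA[s] — reported, then the walk stops
        cur, row = state.toehold, None
        back = 0
        # the bound back < width-1 also covers m = 0, where PLCP never drops
        while back < width - 1 and self.plcp.plcp(cur) >= m:
            cur, row = phi(cur, row)
            starts.append(cur)
            back += 1
        # forward: the remaining count is now known exactly
        cur, row = state.toehold, None
        for _ in range(width - 1 - back):
            cur, row = phi_inv(cur, row)
            starts.append(cur)
        if len(starts) != width:
            raise LocateError(
                f"located {len(starts)} starts for an interval of width {width}"
            )
        return starts
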