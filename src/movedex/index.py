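"""Index assembly: build every component of the bidirectional index at once.

The built index bundles the forward and reverse LF move tables with their SA
samples (for extensions and toehold updates), the balanced phi / inverse-phi
move tables with sparse PLCP samples (for locating), and the fragment
boundary table of the concatenated text (for reporting). Building is done
in memory from suffix structures; the phi tables are optional at build time,
trading locate speed for index size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .bisearch import BiSearcher, SASamples
from .locate import Locator, PLCPSamples
from .movetables import MoveTable, balance, build_lf_table, build_phi_tables
from .textcore import (
    SuffixStructures,
    Text,
    build_suffix_structures,
    concat_with_sentinel,
    fragment_boundaries,
    reverse_text,
)


@dataclass
class BuildConfig:
    """Build-time options.

    with_phi_tables: include balanced phi move tables for fast locating;
        without them, sparse fallback structures are retained instead.
    balance_d: phi-table balancing threshold (max input starts per output
        interval); must be >= 2. 2 is the tightest split, giving the
        strongest fast-forward cap at the price of more rows.
    """

    with_phi_tables: bool = True
    balance_d: int = 2

    def __post_init__(self):
        if self.balance_d < 2:
            raise ValueError("balance_d must be >= 2")


@dataclass
class MoveIndex:
    """A fully built bidirectional move-structure index."""

    n: int
    config: BuildConfig
    mlf: MoveTable
    mlfrev: MoveTable
    samples_fwd: SASamples
    samples_rev: SASamples
    plcp: PLCPSamples
    fragments: list[tuple[str, int, int]]
    mphi: MoveTable | None = None
    mphiinv: MoveTable | None = None
    fallback_sa: list[int] | None = None
    searcher: BiSearcher = field(init=False)
    locator: Locator = field(init=False)

    def __post_init__(self):
        self.searcher = BiSearcher(
            self.mlf, self.mlfrev, self.samples_fwd, self.samples_rev, self.n
        )
        fallback = None
        if self.fallback_sa is not None:
            fallback = _PhiFallback(self.fallback_sa)
        self.locator = Locator(
            self.plcp, self.n, mphi=self.mphi, mphiinv=self.mphiinv,
            fallback=fallback,
        )

    @property
    def r(self) -> int:
        """Number of BWT runs of the forward text."""
        return self.mlf.nrows - 1

    @property
    def rrev(self) -> int:
        return self.mlfrev.nrows - 1

    def fragment_of(self, start: int, length: int):
        """The fragment fully containing [start, start+length), or None."""
        from bisect import bisect_right

        starts = [f[1] for f in self.fragments]
        idx = bisect_right(starts, start) - 1
        if idx < 0:
            return None
        name, fstart, fend = self.fragments[idx]
        if start + length <= fend:
            return self.fragments[idx]
        return None

    def stats(self) -> dict:
        out = {
            "n": self.n,
            "r": self.r,
            "r_rev": self.rrev,
            "with_phi_tables": self.mphi is not None,
        }
        if self.mphi is not None:
            out["phi_rows_balanced"] = self.mphi.nrows - 1
            out["phi_inv_rows_balanced"] = self.mphiinv.nrows - 1
        return out


class _PhiFallback:
    """SA/ISA wrapper so the phi oracles can run on a loaded index."""

    def __init__(self, sa):
        import numpy as np

        self.sa = np.asarray(sa, dtype=np.int64)
        self.n = len(self.sa)
        self.isa = np.empty(self.n, dtype=np.int64)
        self.isa[self.sa] = np.arange(self.n)


def build_index(fragments: list[Text], config: BuildConfig | None = None,
                ) -> MoveIndex:
    """Build the full index from reference fragments."""
    config = config or BuildConfig()
    text = concat_with_sentinel(fragments)
    ss = build_suffix_structures(text)
    ssr = build_suffix_structures(reverse_text(text))
    return build_index_from_structures(ss, ssr, fragment_boundaries(fragments),
                                       config)


def build_index_from_structures(ss: SuffixStructures, ssr: SuffixStructures,
                                fragments, config: BuildConfig) -> MoveIndex:
    mlf = build_lf_table(ss, "lf")
    mlfrev = build_lf_table(ssr, "lfrev")
    samples_fwd = SASamples.from_structures(ss, mlf)
    samples_rev = SASamples.from_structures(ssr, mlfrev)

    phi_unbal, phiinv_unbal = build_phi_tables(ss)
    # the phi input-interval starts are exactly the irreducible PLCP positions
    plcp_positions = [phi_unbal.row_p(j) for j in range(phi_unbal.nrows - 1)]
    plcp = PLCPSamples.from_structures(ss, plcp_positions)

    mphi = mphiinv = fallback_sa = None
    if config.with_phi_tables:
        mphi = balance(phi_unbal, config.balance_d)
        mphiinv = balance(phiinv_unbal, config.balance_d)
    else:
        fallback_sa = [int(v) for v in ss.sa]

    return MoveIndex(
        n=ss.n, config=config, mlf=mlf, mlfrev=mlfrev,
        samples_fwd=samples_fwd, samples_rev=samples_rev, plcp=plcp,
        fragments=list(fragments), mphi=mphi, mphiinv=mphiinv,
        fallback_sa=fallback_sa,
    )
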