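"""Lossless approximate pattern matching via search schemes.

A search scheme splits the pattern into parts and prescribes, for each of its
searches, a processing order over the parts (connected: each prefix of the
order covers a contiguous pattern region) together with cumulative lower and
upper error bounds. Executed over the bidirectional index, every error
distribution of at most K errors is covered by at least one search, so the
union of all searches reports *every* occurrence within distance K — the
scheme is lossless. The default scheme is the pigeonhole scheme: K+1 parts,
each search anchoring one part error-free and extending outward with up to K
errors.

Hamming matching counts mismatches per extension; edit distance maintains a
banded dynamic-programming row per part along the extensions, committing a
cumulative distance at part boundaries. Occurrences are located via the
toehold + phi walks and reduced by an explicit deduplication rule shared
with the brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from .occurrence import FORWARD, REVERSE, Occurrence
from .textcore import SIGMA, reverse_complement

BIG = 10 ** 9


@dataclass(frozen=True)
class Search:
    """One search: part order pi with cumulative error bounds L <= U."""

    pi: tuple[int, ...]
    L: tuple[int, ...]
    U: tuple[int, ...]

    def __post_init__(self):
        t = len(self.pi)
        if not (len(self.L) == len(self.U) == t):
            raise ValueError("pi, L, U must have equal length")
        if sorted(self.pi) != list(range(t)):
            raise ValueError("pi must be a permutation of the part indices")
        for a in range(1, t):
            covered = sorted(self.pi[: a + 1])
            if covered != list(range(covered[0], covered[-1] + 1)):
                raise ValueError("pi must be connected")
        if any(l > u for l, u in zip(self.L, self.U)):
            raise ValueError("L must be pointwise <= U")
        if any(b < a for a, b in zip(self.L, self.L[1:])) or any(
            b < a for a, b in zip(self.U, self.U[1:])
        ):
            raise ValueError("L and U must be non-decreasing")


@dataclass(frozen=True)
class SearchScheme:
    parts: int
    searches: tuple[Search, ...]

    def __post_init__(self):
        if any(len(s.pi) != self.parts for s in self.searches):
            raise ValueError("every search must order all parts")

    def covers(self, errors: tuple[int, ...]) -> bool:
        """Does some search admit this per-part error distribution?"""
        for s in self.searches:
            cum = 0
            ok = True
            for t, part in enumerate(s.pi):
                cum += errors[part]
                if not (s.L[t] <= cum <= s.U[t]):
                    ok = False
                    break
            if ok:
                return True
        return False

    def is_lossless(self, k: int) -> bool:
        """Exhaustively check coverage of every distribution summing to <= k."""
        for errors in product(range(k + 1), repeat=self.parts):
            if sum(errors) <= k and not self.covers(errors):
                return False
        return True


def pigeonhole_scheme(k: int) -> SearchScheme:
    """K+1 parts; search i anchors part i exactly, then extends outward."""
    if k < 0:
        raise ValueError("k must be >= 0")
    parts = k + 1
    searches = []
    for i in range(parts):
        pi = tuple(range(i, parts)) + tuple(range(i - 1, -1, -1))
        U = (0,) + (k,) * (parts - 1)
        L = (0,) * parts
        searches.append(Search(pi, L, U))
    return SearchScheme(parts, tuple(searches))


def parse_scheme(text: str) -> SearchScheme:
    """Parse an explicit scheme: one search per line, 'pi | L | U' with
    comma-separated integers; blank lines and #-comments ignored."""
    searches = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = [f.strip() for f in line.split("|")]
        if len(fields) != 3:
            raise ValueError(f"expected 'pi | L | U', got {line!r}")
        pi, L, U = (tuple(int(x) for x in f.split(",")) for f in fields)
        searches.append(Search(pi, L, U))
    if not searches:
        raise ValueError("scheme file contains no searches")
    return SearchScheme(len(searches[0].pi), tuple(searches))


def partition_pattern(pattern: str, parts: int) -> list[tuple[int, int]]:
    """Uniform half-open piece spans; the remainder goes to the leftmost pieces."""
    m = len(pattern)
    if parts < 1 or m < parts:
        raise ValueError(f"cannot split a length-{m} pattern into {parts} parts")
    base, rem = divmod(m, parts)
    spans = []
    pos = 0
    for i in range(parts):
        size = base + (1 if i < rem else 0)
        spans.append((pos, pos + size))
        pos += size
    return spans


# ---------------------------------------------------------------------------
# search execution


class SchemeRunner:
    """Executes one search scheme for one pattern over a built index."""

    def __init__(self, index, pattern: str, k: int, metric: str,
                 scheme: SearchScheme, strand: str = FORWARD,
                 use_phi_tables: bool = True):
        self.index = index
        self.searcher = index.searcher
        self.locator = index.locator
        self.pattern = pattern
        self.k = k
        self.metric = metric
        self.scheme = scheme
        self.strand = strand
        self.use_phi_tables = use_phi_tables
        self.spans = partition_pattern(pattern, scheme.parts)
        self.raw: list[Occurrence] = []

    def run(self) -> list[Occurrence]:
        for search in self.scheme.searches:
            self._run_search(search)
        return self.raw

    # -- shared helpers -----------------------------------------------------

    def _piece_chars(self, part: int, leftward: bool) -> str:
        lo, hi = self.spans[part]
        piece = self.pattern[lo:hi]
        return piece[::-1] if leftward else piece

    def _direction(self, search: Search, t: int) -> bool:
        """True when part search.pi[t] is matched leftward."""
        if t == 0:
            if len(search.pi) == 1:
                return True
            return search.pi[1] > search.pi[0]
        return search.pi[t] < search.pi[0]

    def _extend(self, state, c: str, leftward: bool):
        if leftward:
            state = self.searcher.switch_direction(state, "forward")
            return self.searcher.add_char_left(state, c)
        state = self.searcher.switch_direction(state, "reverse")
        return self.searcher.add_char_right(state, c)

    def _emit(self, state, distance: int) -> None:
        if self.use_phi_tables and self.locator.has_tables:
            starts = self.locator.locate_all(state)
        else:
            starts = self.locator.locate_all_no_tables(state)
        for start in starts:
            self.raw.append(
                Occurrence(start, state.m, distance, self.strand, self.metric)
            )

    # -- per-search drivers -------------------------------------------------

    def _run_search(self, search: Search) -> None:
        state = self.searcher.initial_state()
        if self.metric == "hamming":
            self._ham_piece(search, 0, state, 0)
        else:
            self._edit_piece(search, 0, state, 0)

    def _ham_piece(self, search: Search, t: int, state, errors: int) -> None:
        leftward = self._direction(search, t)
        chars = self._piece_chars(search.pi[t], leftward)
        self._ham_extend(search, t, state, errors, chars, 0, leftward)

    def _ham_extend(self, search, t, state, errors, chars, q, leftward) -> None:
        if q == len(chars):
            if search.L[t] <= errors <= search.U[t]:
                if t + 1 == len(search.pi):
                    self._emit(state, errors)
                else:
                    self._ham_piece(search, t + 1, state, errors)
            return
        expected = chars[q]
        for a in SIGMA:
            err2 = errors + (a != expected)
            if err2 > search.U[t]:
                continue
            nxt = self._extend(state, a, leftward)
            if nxt is not None:
                self._ham_extend(search, t, nxt, err2, chars, q + 1, leftward)

    def _edit_piece(self, search: Search, t: int, state, base: int) -> None:
        leftward = self._direction(search, t)
        chars = self._piece_chars(search.pi[t], leftward)
        row = [base + j for j in range(len(chars) + 1)]
        self._edit_extend(search, t, state, chars, row, leftward)

    def _edit_extend(self, search, t, state, chars, row, leftward) -> None:
        # commit the part boundary at this text length if within bounds
        final = row[-1]
        if search.L[t] <= final <= search.U[t]:
            if t + 1 == len(search.pi):
                if state.m > 0:
                    self._emit(state, final)
            else:
                self._edit_piece(search, t + 1, state, final)
        if min(row) >= search.U[t] + 1:
            return
        # also stop growing the text once insertions alone exceed the band
        for a in SIGMA:
            new = [row[0] + 1]
            for j in range(1, len(row)):
                new.append(
                    min(
                        row[j - 1] + (a != chars[j - 1]),
                        row[j] + 1,
                        new[j - 1] + 1,
                    )
                )
            if min(new) > search.U[t]:
                continue
            nxt = self._extend(state, a, leftward)
            if nxt is not None:
                self._edit_extend(search, t, nxt, chars, new, leftward)


def run_search_scheme(index, pattern: str, k: int, metric: str = "hamming",
                      scheme: SearchScheme | None = None,
                      strand: str = FORWARD,
                      use_phi_tables: bool = True) -> set[Occurrence]:
    """All occurrences of ``pattern`` within distance k, deduplicated."""
    if scheme is None:
        scheme = pigeonhole_scheme(k)
    if len(pattern) < scheme.parts or not set(pattern) <= set(SIGMA):
        return set()
    runner = SchemeRunner(index, pattern, k, metric, scheme, strand,
                          use_phi_tables)
    return dedup_occurrences(runner.run(), metric=metric, k=k)


# ---------------------------------------------------------------------------
# deduplication (the exact same rule is applied to the brute-force oracle)


def dedup_occurrences(raw, metric: str = "hamming", k: int = 0):
    """Reduce raw hits to a canonical occurrence set.

    Hamming: unique by (strand, start), minimum distance.
    Edit: canonicalize per (strand, start) to the minimum distance and, on
    ties, the shortest length; then collapse hits describing the same
    alignment region — same strand with both endpoints within k — keeping
    the smallest distance, then smallest start, then shortest length.
    """
    if metric == "hamming":
        best: dict = {}
        for occ in raw:
            key = (occ.strand, occ.start)
            if key not in best or occ.distance < best[key].distance:
                best[key] = occ
        return set(best.values())

    per_start: dict = {}
    for occ in raw:
        key = (occ.strand, occ.start)
        cur = per_start.get(key)
        if cur is None or (occ.distance, occ.length) < (cur.distance, cur.length):
            per_start[key] = occ
    accepted: list[Occurrence] = []
    for occ in sorted(per_start.values(),
                      key=lambda o: (o.distance, o.start, o.length)):
        end = occ.start + occ.length
        clash = any(
            a.strand == occ.strand
            and abs(a.start - occ.start) <= k
            and abs((a.start + a.length) - end) <= k
            for a in accepted
        )
        if not clash:
            accepted.append(occ)
    return set(accepted)


# ---------------------------------------------------------------------------
# read-level interface


def align_read(index, read: str, k: int, metric: str = "hamming",
               scheme: SearchScheme | None = None,
               use_phi_tables: bool = True) -> set[Occurrence]:
    """Occurrences of the read and of its reverse complement, strand-tagged.

    Reads containing symbols outside {A,C,G,T} are reported unmapped (empty
    set); matches spanning a fragment boundary of the concatenated text are
    concatenation artifacts and are discarded.
    """
    if not read or not set(read) <= set(SIGMA):
        return set()
    hits = run_search_scheme(index, read, k, metric, scheme, FORWARD,
                             use_phi_tables)
    hits |= run_search_scheme(index, reverse_complement(read), k, metric,
                              scheme, REVERSE, use_phi_tables)
    return {o for o in hits if index.fragment_of(o.start, o.length) is not None}


# ---------------------------------------------------------------------------
# SAM reporting


def sam_header(fragments) -> list[str]:
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for name, start, end in fragments:
        lines.append(f"@SQ\tSN:{name}\tLN:{end - start}")
    return lines


def sam_lines(read_name: str, read_seq: str, occurrences, index) -> list[str]:
    """One SAM line per occurrence (no CIGAR; NM carries the distance)."""
    if not occurrences:
        return [
            f"{read_name}\t4\t*\t0\t0\t*\t*\t0\t0\t{read_seq or '*'}\t*"
        ]
    lines = []
    for occ in sorted(occurrences):
        frag = index.fragment_of(occ.start, occ.length)
        name, fstart, _ = frag
        flag = 16 if occ.strand == REVERSE else 0
        seq = reverse_complement(read_seq) if occ.strand == REVERSE else read_seq
        pos = occ.start - fstart + 1  # SAM is 1-based
        lines.append(
            f"{read_name}\t{flag}\t{name}\t{pos}\t255\t*\t*\t0\t0\t{seq}\t*"
            f"\tNM:i:{occ.distance}"
        )
    return lines
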