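"""Text ingestion, suffix structures, and brute-force reference oracles.

Everything else in the package is validated against the functions here: the
suffix array, BWT and LCP are built directly from definitions, and the
``*_oracle`` functions compute LF, phi, inverse phi and approximate
occurrences by exhaustive means. These run in O(n log n) / O(n * m) time and
are intended for construction and testing at desk scale, not for querying
large pan-genomes (that is what the move tables are for).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SENTINEL = "$"
SIGMA = "ACGT"
#: symbol order $ < A < C < G < T, internal codes 0..4
ALPHABET = SENTINEL + SIGMA
CODE = {c: i for i, c in enumerate(ALPHABET)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA/FASTQ input."""


class IngestError(ValueError):
    """Raised when a sequence contains a symbol outside {A,C,G,T,N}."""


@dataclass(frozen=True)
class Text:
    """A sequence over {A,C,G,T}, optionally terminated by the sentinel '$'.

    A *fragment* (one FASTA record after N-removal) has no sentinel; the
    concatenated search text carries exactly one sentinel at its last
    position. The sentinel sorts before every other symbol.
    """

    symbols: str
    name: str = ""

    @property
    def n(self) -> int:
        return len(self.symbols)

    def __post_init__(self) -> None:
        body, tail = self.symbols[:-1], self.symbols[-1:]
        if SENTINEL in body or not set(body) <= set(SIGMA):
            bad = next(c for c in body if c not in SIGMA)
            raise IngestError(f"symbol {bad!r} not allowed in record {self.name!r}")
        if tail and tail not in SIGMA and tail != SENTINEL:
            raise IngestError(f"symbol {tail!r} not allowed in record {self.name!r}")

    @property
    def has_sentinel(self) -> bool:
        return self.symbols.endswith(SENTINEL)

    def codes(self) -> np.ndarray:
        """Integer codes ($=0, A=1, C=2, G=3, T=4) as an int64 array."""
        return np.frombuffer(
            self.symbols.translate(_CODE_TABLE).encode("latin-1"), dtype=np.uint8
        ).astype(np.int64)


_CODE_TABLE = str.maketrans({c: chr(i) for c, i in CODE.items()})


def read_fasta(path) -> list[Text]:
    """Read a (possibly line-wrapped, multi-record) FASTA file into fragments.

    Sequences are upper-cased and 'N' characters are deleted; any other
    symbol outside {A,C,G,T} raises :class:`IngestError`. Record order is
    preserved.
    """
    fragments: list[Text] = []
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    fragments.append(_make_fragment(name, chunks))
                name = line[1:].split()[0] if len(line) > 1 else f"record{len(fragments)}"
                chunks = []
            else:
                if name is None:
                    raise FastaParseError(
                        f"line {lineno}: sequence data before any '>' header"
                    )
                chunks.append(line)
    if name is None:
        raise FastaParseError("no FASTA records found")
    fragments.append(_make_fragment(name, chunks))
    return fragments


@dataclass(frozen=True)
class ReadRecord:
    """A query read. Unlike reference fragments, symbols are not validated:
    a read with characters outside {A,C,G,T} is later reported unmapped."""

    name: str
    seq: str


def read_fastq(path) -> list[ReadRecord]:
    """Read FASTQ reads (qualities ignored)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln]
    if len(lines) % 4 != 0:
        raise FastaParseError("truncated FASTQ: record count not a multiple of 4")
    reads = []
    for i in range(0, len(lines), 4):
        head, seq, plus = lines[i], lines[i + 1], lines[i + 2]
        if not head.startswith("@") or not plus.startswith("+"):
            raise FastaParseError(f"line {i + 1}: malformed FASTQ record")
        reads.append(ReadRecord(head[1:].split()[0], seq.upper()))
    return reads


def read_queries(path) -> list[ReadRecord]:
    """Read query reads from FASTA or FASTQ (sniffed from the first byte)."""
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        return read_fastq(path)
    reads = []
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    reads.append(ReadRecord(name, "".join(chunks).upper()))
                name = line[1:].split()[0] if len(line) > 1 else f"read{len(reads)}"
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        reads.append(ReadRecord(name, "".join(chunks).upper()))
    return reads


def _make_fragment(name: str, chunks: list[str]) -> Text:
    seq = "".join(chunks).upper().replace("N", "")
    return Text(seq, name=name)


def concat_with_sentinel(fragments: list[Text]) -> Text:
    """Concatenate fragments into the search text and append the sentinel."""
    if not fragments or all(f.n == 0 for f in fragments):
        raise ValueError("need at least one nonempty fragment")
    return Text(
        "".join(f.symbols for f in fragments) + SENTINEL,
        name=fragments[0].name if len(fragments) == 1 else "concat",
    )


def fragment_boundaries(fragments: list[Text]) -> list[tuple[str, int, int]]:
    """(name, start, end) half-open spans of each fragment in the concatenation."""
    spans = []
    pos = 0
    for f in fragments:
        spans.append((f.name, pos, pos + f.n))
        pos += f.n
    return spans


def reverse_text(text: Text) -> Text:
    """Reverse of T's sentinel-free body, re-terminated with '$'."""
    if not text.has_sentinel:
        raise ValueError("reverse_text expects a sentinel-terminated text")
    return Text(text.symbols[-2::-1] + SENTINEL, name=text.name + "_rev")


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(seq))


@dataclass
class SuffixStructures:
    """Suffix array, its inverse, the BWT and the LCP array of one text.

    All are built directly from definitions: SA sorts suffixes, ISA inverts
    it, BWT[i] = T[(SA[i] + n - 1) mod n], and LCP[i] is the longest common
    prefix of the suffixes ranked i-1 and i (LCP[0] = 0).
    """

    text: Text
    sa: np.ndarray
    isa: np.ndarray
    bwt: str
    lcp: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return self.text.n


def build_suffix_structures(text: Text) -> SuffixStructures:
    if not text.has_sentinel or text.n < 1:
        raise ValueError("suffix structures require a sentinel-terminated text")
    codes = text.codes()
    sa = _suffix_array(codes)
    n = text.n
    isa = np.empty(n, dtype=np.int64)
    isa[sa] = np.arange(n)
    bwt_codes = codes[(sa + n - 1) % n]
    bwt = "".join(ALPHABET[c] for c in bwt_codes)
    lcp = _kasai_lcp(codes, sa, isa)
    return SuffixStructures(text=text, sa=sa, isa=isa, bwt=bwt, lcp=lcp)


def _suffix_array(codes: np.ndarray) -> np.ndarray:
    """Deterministic prefix-doubling suffix sort (O(n log^2 n) with numpy)."""
    n = len(codes)
    # densify so that max(rank) == n-1 holds exactly when all ranks differ
    _, rank = np.unique(codes, return_inverse=True)
    rank = rank.astype(np.int64)
    k = 1
    order = np.argsort(rank, kind="stable")
    while rank[order[-1]] != n - 1:
        second = np.full(n, -1, dtype=np.int64)
        second[: n - k] = rank[k:]
        order = np.lexsort((second, rank))
        changed = (rank[order][1:] != rank[order][:-1]) | (
            second[order][1:] != second[order][:-1]
        )
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.concatenate(([0], np.cumsum(changed)))
        rank = new_rank
        k *= 2
    return order


def _kasai_lcp(codes: np.ndarray, sa: np.ndarray, isa: np.ndarray) -> np.ndarray:
    n = len(codes)
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    for i in range(n):
        r = isa[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and codes[i + h] == codes[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


# ---------------------------------------------------------------------------
# reference oracles


def lf_oracle(ss: SuffixStructures, i: int) -> int:
    """LF mapping computed from SA/ISA: ISA[(SA[i] + n - 1) mod n]."""
    if not 0 <= i < ss.n:
        raise IndexError(f"SA index {i} out of range [0, {ss.n})")
    return int(ss.isa[(ss.sa[i] + ss.n - 1) % ss.n])


def phi_oracle(ss: SuffixStructures, i: int) -> int:
    """phi(i): the SA value preceding i in suffix order (wraps at rank 0)."""
    if not 0 <= i < ss.n:
        raise IndexError(f"text position {i} out of range [0, {ss.n})")
    r = int(ss.isa[i])
    return int(ss.sa[r - 1]) if r > 0 else int(ss.sa[ss.n - 1])


def phi_inv_oracle(ss: SuffixStructures, i: int) -> int:
    """Inverse of phi: the SA value following i in suffix order (wraps at rank n-1)."""
    if not 0 <= i < ss.n:
        raise IndexError(f"text position {i} out of range [0, {ss.n})")
    r = int(ss.isa[i])
    return int(ss.sa[r + 1]) if r < ss.n - 1 else int(ss.sa[0])


def interval_oracle(ss: SuffixStructures, pattern: str) -> tuple[int, int]:
    """Closed SA interval [s, e] of suffixes prefixed by ``pattern`` (s > e if none)."""
    import bisect

    suffixes = [ss.text.symbols[p:] for p in ss.sa]
    lo = bisect.bisect_left(suffixes, pattern)
    hi = bisect.bisect_right(suffixes, pattern + "\x7f")
    return lo, hi - 1


def occurrences_oracle(text: Text, pattern: str, k: int, metric: str = "hamming",
                       strand: str = "+"):
    """Exhaustive-scan occurrence finder (the ground truth for the index).

    Hamming: every start whose full-length window has <= k mismatches.
    Edit: for every start, the minimum edit distance over candidate lengths
    (shortest length on ties); hits are then reduced by the same
    deduplication rule the aligner uses, so both sides agree exactly.
    """
    from .occurrence import Occurrence

    if metric not in ("hamming", "edit"):
        raise ValueError(f"unknown metric {metric!r}")
    m = len(pattern)
    if m == 0 or not set(pattern) <= set(SIGMA):
        return set()
    body = text.symbols[:-1] if text.has_sentinel else text.symbols
    n_body = len(body)
    if metric == "hamming":
        if m > n_body:
            return set()
        codes = np.frombuffer(body.encode("latin-1"), dtype=np.uint8)
        pat = np.frombuffer(pattern.encode("latin-1"), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(codes, m)
        dists = (windows != pat).sum(axis=1)
        return {
            Occurrence(int(s), m, int(d), strand, "hamming")
            for s, d in enumerate(dists)
            if d <= k
        }
    raw = _edit_scan(body, pattern, k, strand)
    from .apm import dedup_occurrences

    return dedup_occurrences(raw, metric="edit", k=k)


def _edit_scan(body: str, pattern: str, k: int, strand: str):
    """Banded semi-global DP, vectorized across all start positions."""
    from .occurrence import Occurrence

    m = len(pattern)
    n_body = len(body)
    lmin = max(1, m - k)
    if lmin > n_body:
        return []
    width = m + k
    pad = 5  # code matching nothing
    codes = np.frombuffer(body.encode("latin-1"), dtype=np.uint8).astype(np.int16)
    padded = np.concatenate([codes, np.full(width, pad, dtype=np.int16)])
    starts = n_body  # candidate starts 0..n_body-1
    win = np.lib.stride_tricks.sliding_window_view(padded, width)[:starts]
    pat = np.frombuffer(pattern.encode("latin-1"), dtype=np.uint8).astype(np.int16)

    big = np.int32(10 ** 6)
    idx = np.arange(width + 1, dtype=np.int32)
    prev = np.broadcast_to(idx, (starts, width + 1)).copy()
    for j in range(1, m + 1):
        sub = prev[:, :-1] + (win != pat[j - 1])
        up = prev[:, 1:] + 1
        cand = np.minimum(sub, up).astype(np.int32)
        # resolve the horizontal (insertion) dependency with a running min
        shifted = np.concatenate(
            [np.full((starts, 1), j, dtype=np.int32), cand - idx[1:]], axis=1
        )
        row = np.minimum.accumulate(shifted, axis=1) + idx
        prev = row
    final = prev  # final[s, l] = dist(pattern, body[s:s+l]) within the band
    # mask out lengths outside [lmin, m+k] or running past the text body
    maxlen = np.minimum(width, n_body - np.arange(starts))
    mask = (idx >= lmin) & (idx[None, :] <= maxlen[:, None])
    scored = np.where(mask, final, big)
    best_len = np.argmin(scored, axis=1)  # smallest length on ties
    best = scored[np.arange(starts), best_len]
    return [
        Occurrence(int(s), int(best_len[s]), int(best[s]), strand, "edit")
        for s in range(starts)
        if best[s] <= k
    ]
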