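"""Bit-packed move-table rows and whole-index serialization.

A full (in-memory) move table spends a machine word per field. The packed
representation gives each field its dedicated number of bits — ceil(log2)
of its value range — and stores all rows in one contiguous byte block,
each row starting on a byte boundary so that reading row j touches exactly
bytesPerRow bytes. Packed tables implement the same row-access protocol as
full tables, so move_step and everything above it runs on either
representation unchanged.

The on-disk container is a little-endian custom format (magic ``MVDX``,
versioned); it stores the packed LF tables, optional packed phi tables, SA
samples, PLCP samples, and the fragment-boundary table.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

from .bisearch import SASamples
from .index import BuildConfig, MoveIndex
from .locate import PLCPSamples
from .movetables import MoveTable, StepStats

MAGIC = b"MVDX"
VERSION = 1

#: 3-bit character codes; 5 marks the (blank) sentinel row of LF tables
CHAR_CODES = {"$": 0, "A": 1, "C": 2, "G": 3, "T": 4, "": 5}
CODE_CHARS = {v: k for k, v in CHAR_CODES.items()}


class PackError(ValueError):
    """A field value does not fit its declared bit width (a layout bug)."""


class IndexFormatError(ValueError):
    """Bad magic, version, or internally inconsistent index file."""


@dataclass(frozen=True)
class RowLayout:
    char_bits: int
    pos_bits: int  # p and pi
    xi_bits: int

    @property
    def bits_per_row(self) -> int:
        return self.char_bits + 2 * self.pos_bits + self.xi_bits

    @property
    def bytes_per_row(self) -> int:
        return -(-self.bits_per_row // 8)


def row_layout(n: int, rows: int, has_char: bool) -> RowLayout:
    """Field widths: p and pi take ceil(log2) bits for values up to n (the
    sentinel row stores p = n), xi takes ceil(log2 rows) bits, plus 3 bits
    for the run character in LF tables. Widths are floored at 1 bit so
    degenerate tables still encode."""
    if n < 2 or rows < 1:
        raise ValueError("need n >= 2 and rows >= 1")
    pos_bits = max(1, int(np.ceil(np.log2(n + 1))))
    xi_bits = max(1, int(np.ceil(np.log2(rows)))) if rows > 1 else 1
    return RowLayout(3 if has_char else 0, pos_bits, xi_bits)


def encode_row(layout: RowLayout, c: str | None, p: int, pi: int, xi: int) -> bytes:
    value = 0
    shift = 0
    fields = []
    if layout.char_bits:
        fields.append((CHAR_CODES[c], layout.char_bits, "c"))
    fields += [(p, layout.pos_bits, "p"), (pi, layout.pos_bits, "pi"),
               (xi, layout.xi_bits, "xi")]
    for v, bits, name in fields:
        if not 0 <= v < (1 << bits):
            raise PackError(f"field {name}={v} does not fit in {bits} bits")
        value |= v << shift
        shift += bits
    return value.to_bytes(layout.bytes_per_row, "little")


def decode_row(layout: RowLayout, raw: bytes):
    value = int.from_bytes(raw, "little")
    c = None
    if layout.char_bits:
        c = CODE_CHARS[value & ((1 << layout.char_bits) - 1)]
        value >>= layout.char_bits
    p = value & ((1 << layout.pos_bits) - 1)
    value >>= layout.pos_bits
    pi = value & ((1 << layout.pos_bits) - 1)
    value >>= layout.pos_bits
    xi = value & ((1 << layout.xi_bits) - 1)
    return c, p, pi, xi


class PackedTable:
    """Bit-packed move table exposing the full tables' row-access protocol."""

    def __init__(self, kind: str, n: int, nrows: int, layout: RowLayout,
                 data: bytes, balanced: bool = False):
        if len(data) != nrows * layout.bytes_per_row:
            raise IndexFormatError("packed data length does not match row count")
        self.kind = kind
        self.n = n
        self._nrows = nrows
        self.layout = layout
        self.data = data
        self.balanced = balanced
        self.ff_stats = StepStats()

    @property
    def nrows(self) -> int:
        return self._nrows

    @property
    def has_chars(self) -> bool:
        return self.layout.char_bits > 0

    def _raw(self, j: int) -> bytes:
        b = self.layout.bytes_per_row
        return self.data[b * j:b * (j + 1)]

    def row_tuple(self, j: int):
        return decode_row(self.layout, self._raw(j))

    def row_p(self, j: int) -> int:
        return self.row_tuple(j)[1]

    def row_pi(self, j: int) -> int:
        return self.row_tuple(j)[2]

    def row_xi(self, j: int) -> int:
        return self.row_tuple(j)[3]

    def row_char(self, j: int):
        return self.row_tuple(j)[0]

    def row(self, j: int):
        from .movetables import MoveRow

        c, p, pi, xi = self.row_tuple(j)
        return MoveRow(c, p, pi, xi)

    def rows(self):
        return [self.row(j) for j in range(self.nrows)]


def pack_table(table: MoveTable) -> PackedTable:
    layout = row_layout(table.n, table.nrows, table.has_chars)
    chunks = []
    for j in range(table.nrows):
        chunks.append(
            encode_row(layout, table.row_char(j), table.row_p(j),
                       table.row_pi(j), table.row_xi(j))
        )
    return PackedTable(table.kind, table.n, table.nrows, layout,
                       b"".join(chunks), balanced=table.balanced)


def unpack_table(packed: PackedTable) -> MoveTable:
    rows = [packed.row_tuple(j) for j in range(packed.nrows)]
    chars = [r[0] for r in rows] if packed.has_chars else None
    return MoveTable(
        packed.kind, packed.n,
        [r[1] for r in rows], [r[2] for r in rows], [r[3] for r in rows],
        chars=chars, balanced=packed.balanced,
    )


def full_table_nbytes(table) -> int:
    """Serialized size of the 64-bit-per-field representation."""
    fields = 4 if table.has_chars else 3
    return table.nrows * fields * 8


# ---------------------------------------------------------------------------
# container I/O


def _w_u64(fh, *values):
    fh.write(struct.pack("<" + "Q" * len(values), *values))


def _r_u64(fh, count=1):
    vals = struct.unpack("<" + "Q" * count, fh.read(8 * count))
    return vals[0] if count == 1 else vals


def _w_array(fh, values):
    arr = np.asarray(values, dtype="<u8")
    _w_u64(fh, len(arr))
    fh.write(arr.tobytes())


def _r_array(fh):
    count = _r_u64(fh)
    return np.frombuffer(fh.read(8 * count), dtype="<u8").astype(np.int64).tolist()


def _w_str(fh, s: str):
    raw = s.encode("utf-8")
    _w_u64(fh, len(raw))
    fh.write(raw)


def _r_str(fh) -> str:
    return fh.read(_r_u64(fh)).decode("utf-8")


_KIND_IDS = {"lf": 0, "lfrev": 1, "phi": 2, "phiinv": 3}
_ID_KINDS = {v: k for k, v in _KIND_IDS.items()}


def _w_table(fh, table) -> None:
    packed = table if isinstance(table, PackedTable) else pack_table(table)
    _w_u64(fh, _KIND_IDS[packed.kind], packed.n, packed.nrows,
           1 if packed.has_chars else 0, 1 if packed.balanced else 0)
    _w_u64(fh, len(packed.data))
    fh.write(packed.data)


def _r_table(fh) -> PackedTable:
    kind_id, n, nrows, has_chars, balanced = _r_u64(fh, 5)
    layout = row_layout(n, nrows, bool(has_chars))
    nbytes = _r_u64(fh)
    data = fh.read(nbytes)
    return PackedTable(_ID_KINDS[kind_id], n, nrows, layout, data,
                       balanced=bool(balanced))


def save_index(index: MoveIndex, path) -> None:
    """Write the whole index as a versioned little-endian container."""
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        _w_u64(fh, VERSION, index.n,
               1 if index.mphi is not None else 0,
               index.config.balance_d)
        _w_u64(fh, len(index.fragments))
        for name, start, end in index.fragments:
            _w_str(fh, name)
            _w_u64(fh, start, end)
        _w_table(fh, index.mlf)
        _w_table(fh, index.mlfrev)
        _w_array(fh, index.samples_fwd.start_sa)
        _w_array(fh, index.samples_fwd.end_sa)
        _w_array(fh, index.samples_rev.start_sa)
        _w_array(fh, index.samples_rev.end_sa)
        _w_array(fh, index.plcp.positions)
        _w_array(fh, index.plcp.values)
        if index.mphi is not None:
            _w_table(fh, index.mphi)
            _w_table(fh, index.mphiinv)
        else:
            _w_array(fh, index.fallback_sa)


def load_index(path, unpack: bool = False) -> MoveIndex:
    """Load an index; tables stay bit-packed unless ``unpack`` is set."""
    try:
        return _load_index(path, unpack)
    except (struct.error, ValueError) as exc:
        if isinstance(exc, IndexFormatError):
            raise
        raise IndexFormatError(f"truncated or corrupt index file: {exc}") from exc


def _load_index(path, unpack: bool) -> MoveIndex:
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic != MAGIC:
            raise IndexFormatError(f"bad magic {magic!r}")
        version, n, has_phi, balance_d = _r_u64(fh, 4)
        if version != VERSION:
            raise IndexFormatError(f"unsupported index version {version}")
        nfrag = _r_u64(fh)
        fragments = []
        for _ in range(nfrag):
            name = _r_str(fh)
            start, end = _r_u64(fh, 2)
            fragments.append((name, start, end))
        mlf = _r_table(fh)
        mlfrev = _r_table(fh)
        samples_fwd = SASamples(_r_array(fh), _r_array(fh))
        samples_rev = SASamples(_r_array(fh), _r_array(fh))
        plcp = PLCPSamples(_r_array(fh), _r_array(fh))
        mphi = mphiinv = fallback_sa = None
        if has_phi:
            mphi = _r_table(fh)
            mphiinv = _r_table(fh)
        else:
            fallback_sa = _r_array(fh)
        if fh.read(1):
            raise IndexFormatError("trailing bytes after index payload")
    for table in (mlf, mlfrev, mphi, mphiinv):
        if table is not None and table.n != n:
            raise IndexFormatError(
                f"header n={n} disagrees with {table.kind} table domain {table.n}"
            )
    if unpack:
        mlf, mlfrev = unpack_table(mlf), unpack_table(mlfrev)
        if mphi is not None:
            mphi, mphiinv = unpack_table(mphi), unpack_table(mphiinv)
    return MoveIndex(
        n=n, config=BuildConfig(with_phi_tables=bool(has_phi),
                                balance_d=balance_d),
        mlf=mlf, mlfrev=mlfrev, samples_fwd=samples_fwd,
        samples_rev=samples_rev, plcp=plcp, fragments=fragments,
        mphi=mphi, mphiinv=mphiinv, fallback_sa=fallback_sa,
    )
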