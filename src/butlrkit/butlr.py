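"""BUTLR-style indexed binary container for sparse contact matrices.

The format stores, per resolution, any number of intra-chromosomal matrices
(upper triangle only) and inter-chromosomal matrices (full rectangle, rows =
the chromosome earlier in the canonical chromosome order).  A directory in
the header maps each matrix to the byte offset of its row index; the row
index delimits each row's record, so a region query seeks directly to the
rows it needs and never scans the whole payload.  That locality is what makes
hosting such a file behind plain HTTP range requests practical.

Byte layout (normative; all integers little-endian; version bump required for
any change):

    magic           8 bytes  = b"BUTLRBIN"
    version         uint16   = 1
    assembly        uint8 length + UTF-8 bytes
    normalization   uint8 length + UTF-8 bytes
    resolution      uint32   (bp per bin)
    n_chrom         uint16
      per chromosome: uint8 name length + UTF-8 name, uint64 length (bp)
    n_matrices      uint16
      per matrix: uint8 kind (0 intra, 1 inter), uint16 chrom_a index,
                  uint16 chrom_b index, uint32 n_rows, uint32 n_cols,
                  uint64 row-index offset
    per matrix, at its offset:
      row index: (n_rows + 1) uint64 absolute byte offsets delimiting rows
      rows: for each nonempty row, uint32 nonzero count, then count uint32
            sorted column ids, then count float32 values; empty rows occupy
            zero bytes (equal consecutive offsets).
"""

from __future__ import annotations

import io
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import BinaryIO, Iterable

import numpy as np
import scipy.sparse as sp

from .errors import (
    CorruptFileError,
    FormatError,
    InvalidParameterError,
    NotFoundError,
)
from .genome import ChromTable, GenomicInterval, make_bin_index
from .matrix import ContactMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MAGIC",
    "VERSION",
    "ButlrHeader",
    "ButlrFile",
    "DirectoryEntry",
    "ValidationReport",
    "encode_butlr",
    "read_header",
    "validate_butlr",
]

MAGIC = b"BUTLRBIN"
VERSION = 1

_KIND_INTRA = 0
_KIND_INTER = 1
_DIR_ENTRY = struct.Struct("<BHHIIQ")


@dataclass(frozen=True)
class DirectoryEntry:
    """One matrix in the header directory."""

    kind: str  # "intra" | "inter"
    chrom_a: str
    chrom_b: str
    n_rows: int
    n_cols: int
    offset: int  # byte offset of the row index

    @property
    def key(self) -> str | tuple[str, str]:
        return self.chrom_a if self.kind == "intra" else (self.chrom_a, self.chrom_b)


@dataclass
class ButlrHeader:
    version: int
    assembly: str
    normalization: str
    resolution: int
    chrom_table: ChromTable
    directory: dict[str | tuple[str, str], DirectoryEntry] = field(default_factory=dict)
    header_size: int = 0


# ----------------------------------------------------------------------
# Encoding

def encode_butlr(
    matrices: Iterable[ContactMatrix],
    chroms: ChromTable,
    resolution: int,
    destination: str | Path,
    assembly: str = "custom",
    normalization: str | None = None,
) -> "ButlrFile":
    """Encode contact matrices into an indexed binary file and reopen it.

    All matrices must share ``resolution`` and have dimensions matching the
    bin counts of ``chroms``.  Intra matrices are stored upper-triangular;
    inter matrices are reoriented so rows belong to the chromosome earlier in
    the canonical order.  Zero values are dropped.
    """
    if resolution <= 0:
        raise InvalidParameterError(f"resolution must be > 0, got {resolution}")
    index = make_bin_index(chroms, resolution)
    prepared: dict[str | tuple[str, str], ContactMatrix] = {}
    norm_label = normalization
    for m in matrices:
        if m.resolution != resolution:
            raise InvalidParameterError(
                f"matrix {m.key} resolution {m.resolution} != file resolution {resolution}"
            )
        if m.chrom_a not in chroms or m.chrom_b not in chroms:
            raise InvalidParameterError(
                f"matrix {m.key} uses chromosomes absent from the table"
            )
        if not m.is_intra and chroms.rank(m.chrom_a) > chroms.rank(m.chrom_b):
            m = ContactMatrix(
                m.chrom_b, m.chrom_a, m.resolution, m.n_cols, m.n_rows,
                m.data.T.tocsr(), m.normalization,
            )
        exp = (index.n_bins(m.chrom_a), index.n_bins(m.chrom_b))
        if (m.n_rows, m.n_cols) != exp:
            raise InvalidParameterError(
                f"matrix {m.key} dims {(m.n_rows, m.n_cols)} != expected {exp} "
                f"for resolution {resolution}"
            )
        if m.key in prepared:
            raise InvalidParameterError(f"duplicate matrix key {m.key}")
        prepared[m.key] = m
        if norm_label is None:
            norm_label = m.normalization
    norm_label = norm_label or "raw"

    # deterministic directory order: intra by rank, then inter by rank pair
    def _order(m: ContactMatrix) -> tuple:
        if m.is_intra:
            return (0, chroms.rank(m.chrom_a), 0)
        return (1, chroms.rank(m.chrom_a), chroms.rank(m.chrom_b))

    ordered = sorted(prepared.values(), key=_order)

    head = io.BytesIO()
    head.write(MAGIC)
    head.write(struct.pack("<H", VERSION))
    _write_str(head, assembly)
    _write_str(head, norm_label)
    head.write(struct.pack("<I", resolution))
    head.write(struct.pack("<H", len(chroms)))
    for name, length in chroms:
        _write_str(head, name)
        head.write(struct.pack("<Q", length))
    head.write(struct.pack("<H", len(ordered)))
    fixed = head.getvalue()
    header_size = len(fixed) + len(ordered) * _DIR_ENTRY.size

    # lay out row indexes and payloads
    cursor = header_size
    dir_entries: list[bytes] = []
    blocks: list[tuple[np.ndarray, ContactMatrix]] = []
    for m in ordered:
        csr = m.data.tocsr()
        csr.sort_indices()
        counts = np.diff(csr.indptr)
        rec_sizes = np.where(counts > 0, 4 + 8 * counts, 0).astype(np.int64)
        index_off = cursor
        payload_start = index_off + 8 * (m.n_rows + 1)
        row_offsets = payload_start + np.concatenate(
            ([0], np.cumsum(rec_sizes))
        ).astype(np.uint64)
        cursor = int(row_offsets[-1])
        kind = _KIND_INTRA if m.is_intra else _KIND_INTER
        dir_entries.append(
            _DIR_ENTRY.pack(kind, chroms.rank(m.chrom_a), chroms.rank(m.chrom_b),
                            m.n_rows, m.n_cols, index_off)
        )
        blocks.append((row_offsets, m))

    with open(destination, "wb") as fh:
        fh.write(fixed)
        for entry in dir_entries:
            fh.write(entry)
        for row_offsets, m in blocks:
            fh.write(row_offsets.astype("<u8").tobytes())
            csr = m.data.tocsr()
            csr.sort_indices()
            for r in range(m.n_rows):
                lo, hi = csr.indptr[r], csr.indptr[r + 1]
                if hi == lo:
                    continue
                cols = csr.indices[lo:hi].astype("<u4")
                vals = csr.data[lo:hi].astype("<f4")
                fh.write(struct.pack("<I", hi - lo))
                fh.write(cols.tobytes())
                fh.write(vals.tobytes())
    logger.info("encoded %d matrices to %s (%d bytes)", len(ordered), destination, cursor)
    return ButlrFile(destination)


def _write_str(fh, s: str) -> None:
    raw = s.encode("utf-8")
    if len(raw) > 255:
        raise InvalidParameterError(f"string too long for format: {s[:32]!r}...")
    fh.write(struct.pack("<B", len(raw)))
    fh.write(raw)


# ----------------------------------------------------------------------
# Decoding

class _CountingReader:
    """Seek/read wrapper that counts payload bytes actually read."""

    def __init__(self, fh: BinaryIO):
        self._fh = fh
        self.bytes_read = 0

    def read_at(self, offset: int, n: int) -> bytes:
        self._fh.seek(offset)
        data = self._fh.read(n)
        self.bytes_read += len(data)
        if len(data) != n:
            raise CorruptFileError(
                f"truncated file: wanted {n} bytes at offset {offset}, got {len(data)}"
            )
        return data

    def read(self, n: int) -> bytes:
        data = self._fh.read(n)
        self.bytes_read += len(data)
        if len(data) != n:
            raise CorruptFileError(f"truncated header: wanted {n} bytes, got {len(data)}")
        return data


def _parse_header(reader: _CountingReader) -> ButlrHeader:
    magic = reader.read(len(MAGIC))
    if magic != MAGIC:
        raise FormatError(f"bad magic {magic!r}; not a BUTLR-style file")
    (version,) = struct.unpack("<H", reader.read(2))
    if version != VERSION:
        raise FormatError(f"unsupported format version {version}")
    assembly = _read_str(reader)
    normalization = _read_str(reader)
    (resolution,) = struct.unpack("<I", reader.read(4))
    (n_chrom,) = struct.unpack("<H", reader.read(2))
    entries = []
    for _ in range(n_chrom):
        name = _read_str(reader)
        (length,) = struct.unpack("<Q", reader.read(8))
        entries.append((name, length))
    chrom_table = ChromTable(entries)
    names = chrom_table.names
    (n_mat,) = struct.unpack("<H", reader.read(2))
    directory: dict[str | tuple[str, str], DirectoryEntry] = {}
    for _ in range(n_mat):
        kind_i, ia, ib, n_rows, n_cols, offset = _DIR_ENTRY.unpack(
            reader.read(_DIR_ENTRY.size)
        )
        if ia >= len(names) or ib >= len(names):
            raise CorruptFileError("directory references unknown chromosome index")
        kind = "intra" if kind_i == _KIND_INTRA else "inter"
        entry = DirectoryEntry(kind, names[ia], names[ib], n_rows, n_cols, offset)
        if entry.key in directory:
            raise CorruptFileError(f"duplicate directory key {entry.key}")
        directory[entry.key] = entry
    return ButlrHeader(
        version=version,
        assembly=assembly,
        normalization=normalization,
        resolution=resolution,
        chrom_table=chrom_table,
        directory=directory,
        header_size=reader.bytes_read,
    )


def _read_str(reader: _CountingReader) -> str:
    (n,) = struct.unpack("<B", reader.read(1))
    return reader.read(n).decode("utf-8")


def read_header(path: str | Path) -> ButlrHeader:
    """Parse and return the header without touching any matrix payload."""
    with open(path, "rb") as fh:
        return _parse_header(_CountingReader(fh))


class ButlrFile:
    """An open BUTLR-style file supporting seek-based region queries.

    Only the header is read at open time; row indexes are read lazily, and a
    query touches only the offset slice and payload rows it needs.  The
    ``bytes_read`` counter exposes the I/O-locality contract for testing.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._fh: BinaryIO | None = open(self.path, "rb")
        self._reader = _CountingReader(self._fh)
        self.header = _parse_header(self._reader)
        self.file_size = self.path.stat().st_size

    # -- plumbing -------------------------------------------------------
    @property
    def chroms(self) -> ChromTable:
        return self.header.chrom_table

    @property
    def resolution(self) -> int:
        return self.header.resolution

    @property
    def bytes_read(self) -> int:
        return self._reader.bytes_read

    def reset_io_counter(self) -> None:
        self._reader.bytes_read = 0

    def matrix_keys(self) -> list[str | tuple[str, str]]:
        return list(self.header.directory)

    def close(self) -> None:
        if self._fh is not None:
            self._fh.close()
            self._fh = None

    def __enter__(self) -> "ButlrFile":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- queries --------------------------------------------------------
    def _entry(self, key: str | tuple[str, str]) -> DirectoryEntry:
        try:
            return self.header.directory[key]
        except KeyError:
            raise NotFoundError(f"matrix {key!r} absent from file directory") from None

    def _row_offsets(self, entry: DirectoryEntry, r0: int, r1: int) -> np.ndarray:
        """Offsets delimiting rows r0..r1 (r1 exclusive): r1 - r0 + 1 values."""
        raw = self._reader.read_at(entry.offset + 8 * r0, 8 * (r1 - r0 + 1))
        return np.frombuffer(raw, dtype="<u8")

    def _bin_span(self, iv: GenomicInterval, chrom: str, n: int) -> tuple[int, int]:
        b0 = min(iv.start // self.resolution, n)
        b1 = min(-(-iv.end // self.resolution), n)
        return b0, max(b0, b1)

    def query(self, a: GenomicInterval, b: GenomicInterval | None = None) -> np.ndarray:
        """Dense rectangle of bins(a) x bins(b); intra views are symmetric.

        Omitting ``b`` gives the square intra view of ``a``.  Bins beyond the
        stored data are zero.
        """
        if b is None:
            b = a
        ca = self.chroms.resolve_name(a.chrom)
        cb = self.chroms.resolve_name(b.chrom)
        if ca == cb:
            return self._query_intra(ca, a, b)
        oa, ob = self.chroms.order_pair(ca, cb)
        entry = self._entry((oa, ob))
        if ca == oa:
            return self._query_inter(entry, a, b, transpose=False)
        return self._query_inter(entry, b, a, transpose=True)

    def _query_intra(self, chrom: str, a: GenomicInterval, b: GenomicInterval) -> np.ndarray:
        entry = self._entry(chrom)
        n = entry.n_rows
        a0, a1 = self._bin_span(a, chrom, n)
        b0, b1 = self._bin_span(b, chrom, n)
        out = np.zeros((a1 - a0, b1 - b0))
        rmin, rmax = min(a0, b0), min(a1, b1)
        if rmax <= rmin or out.size == 0:
            return out
        offs = self._row_offsets(entry, rmin, rmax)
        payload = self._reader.read_at(int(offs[0]), int(offs[-1] - offs[0]))
        base = int(offs[0])
        for k, r in enumerate(range(rmin, rmax)):
            lo, hi = int(offs[k]) - base, int(offs[k + 1]) - base
            if hi == lo:
                continue
            cols, vals = _decode_row(payload[lo:hi], r)
            if a0 <= r < a1:
                m = (cols >= b0) & (cols < b1)
                np.add.at(out[r - a0], cols[m] - b0, vals[m])
            if b0 <= r < b1:
                m = (cols != r) & (cols >= a0) & (cols < a1)
                np.add.at(out[:, r - b0], cols[m] - a0, vals[m])
        return out

    def _query_inter(
        self, entry: DirectoryEntry, row_iv: GenomicInterval,
        col_iv: GenomicInterval, transpose: bool,
    ) -> np.ndarray:
        r0, r1 = self._bin_span(row_iv, entry.chrom_a, entry.n_rows)
        c0, c1 = self._bin_span(col_iv, entry.chrom_b, entry.n_cols)
        out = np.zeros((r1 - r0, c1 - c0))
        if out.size and r1 > r0:
            offs = self._row_offsets(entry, r0, r1)
            payload = self._reader.read_at(int(offs[0]), int(offs[-1] - offs[0]))
            base = int(offs[0])
            for k, r in enumerate(range(r0, r1)):
                lo, hi = int(offs[k]) - base, int(offs[k + 1]) - base
                if hi == lo:
                    continue
                cols, vals = _decode_row(payload[lo:hi], r)
                m = (cols >= c0) & (cols < c1)
                out[r - r0, cols[m] - c0] = vals[m]
        return out.T if transpose else out

    def decode_matrix(self, key: str | tuple[str, str]) -> ContactMatrix:
        """Fully decode one stored matrix back into a ContactMatrix."""
        entry = self._entry(key)
        offs = self._row_offsets(entry, 0, entry.n_rows)
        payload = self._reader.read_at(int(offs[0]), int(offs[-1] - offs[0]))
        base = int(offs[0])
        rows_l, cols_l, vals_l = [], [], []
        for r in range(entry.n_rows):
            lo, hi = int(offs[r]) - base, int(offs[r + 1]) - base
            if hi == lo:
                continue
            cols, vals = _decode_row(payload[lo:hi], r)
            rows_l.append(np.full(len(cols), r, dtype=np.int64))
            cols_l.append(cols)
            vals_l.append(vals)
        if rows_l:
            data = sp.coo_matrix(
                (np.concatenate(vals_l),
                 (np.concatenate(rows_l), np.concatenate(cols_l))),
                shape=(entry.n_rows, entry.n_cols),
            )
        else:
            data = sp.csr_matrix((entry.n_rows, entry.n_cols))
        return ContactMatrix(
            entry.chrom_a, entry.chrom_b, self.resolution,
            entry.n_rows, entry.n_cols, data, self.header.normalization,
        )


def _decode_row(record: bytes, row: int) -> tuple[np.ndarray, np.ndarray]:
    if len(record) < 4:
        raise CorruptFileError(f"row {row}: record shorter than its count field")
    (count,) = struct.unpack_from("<I", record, 0)
    if len(record) != 4 + 8 * count:
        raise CorruptFileError(
            f"row {row}: record length {len(record)} inconsistent with count {count}"
        )
    cols = np.frombuffer(record, dtype="<u4", count=count, offset=4).astype(np.int64)
    vals = np.frombuffer(record, dtype="<f4", count=count, offset=4 + 4 * count).astype(
        np.float64
    )
    return cols, vals


# ----------------------------------------------------------------------
# Validation

@dataclass
class ValidationReport:
    path: str
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.ok:
            return f"{self.path}: OK"
        return f"{self.path}: {len(self.violations)} violation(s)\n" + "\n".join(
            "  - " + v for v in self.violations
        )


def validate_butlr(path: str | Path) -> ValidationReport:
    """Check structural integrity of a file; returns a report of violations.

    Verifies the magic tag and version, offset monotonicity and bounds,
    per-row record consistency, column sorting, upper-triangularity of intra
    matrices, and value finiteness/non-negativity.
    """
    report = ValidationReport(path=str(path))
    file_size = Path(path).stat().st_size
    try:
        with open(path, "rb") as fh:
            reader = _CountingReader(fh)
            try:
                header = _parse_header(reader)
            except (FormatError, CorruptFileError) as exc:
                report.violations.append(f"header: {exc}")
                return report
            for key, entry in header.directory.items():
                pre = f"matrix {key}"
                index_end = entry.offset + 8 * (entry.n_rows + 1)
                if entry.offset < header.header_size or index_end > file_size:
                    report.violations.append(f"{pre}: row index outside file bounds")
                    continue
                offs = np.frombuffer(
                    reader.read_at(entry.offset, 8 * (entry.n_rows + 1)), dtype="<u8"
                )
                if np.any(np.diff(offs.astype(np.int64)) < 0):
                    report.violations.append(f"{pre}: row offsets not non-decreasing")
                    continue
                if int(offs[-1]) > file_size:
                    report.violations.append(
                        f"{pre}: payload truncated (ends at {int(offs[-1])}, "
                        f"file is {file_size} bytes)"
                    )
                    continue
                for r in range(entry.n_rows):
                    lo, hi = int(offs[r]), int(offs[r + 1])
                    if hi == lo:
                        continue
                    try:
                        cols, vals = _decode_row(reader.read_at(lo, hi - lo), r)
                    except CorruptFileError as exc:
                        report.violations.append(f"{pre}: {exc}")
                        continue
                    if np.any(np.diff(cols) <= 0):
                        report.violations.append(
                            f"{pre}: row {r} columns not strictly increasing"
                        )
                    if np.any(cols >= entry.n_cols):
                        report.violations.append(f"{pre}: row {r} column out of range")
                    if entry.kind == "intra" and np.any(cols < r):
                        report.violations.append(
                            f"{pre}: row {r} violates upper-triangularity"
                        )
                    if not np.all(np.isfinite(vals)):
                        report.violations.append(f"{pre}: row {r} has non-finite values")
                    elif np.any(vals < 0):
                        report.violations.append(f"{pre}: row {r} has negative values")
    except OSError as exc:
        report.violations.append(f"I/O error: {exc}")
    return report
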