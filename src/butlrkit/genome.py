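"""Genome coordinate model: chromosomes, fixed-width bins, intervals, queries.

All coordinates are 0-based half-open internally.  Region strings of the form
``chrom:start-end`` (thousands separators tolerated) are likewise read as
0-based half-open, the convention used by most Hi-C tooling, so that
``chr12:15,000,000-25,000,000`` at 25-kb resolution spans exactly 400 bins.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .errors import InvalidParameterError, NotFoundError, QueryParseError

__all__ = [
    "ChromTable",
    "BinIndex",
    "GenomicInterval",
    "AnnotationTable",
    "make_bin_index",
    "resolve_query",
    "render_region",
    "read_chrom_sizes",
    "read_annotation_bed",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise InvalidParameterError("interval chromosome name is empty")
        if not (0 <= self.start < self.end):
            raise InvalidParameterError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def expand(self, flank: int, chrom_length: int | None = None) -> "GenomicInterval":
        """Widen by ``flank`` bp on each side, clipped to the chromosome."""
        start = max(0, self.start - flank)
        end = self.end + flank
        if chrom_length is not None:
            end = min(end, chrom_length)
        return GenomicInterval(self.chrom, start, end)


class ChromTable:
    """Ordered chromosome names and lengths.

    The list order is canonical: it defines chromosome rank, which fixes the
    orientation (rows vs columns) of inter-chromosomal matrices.
    """

    def __init__(self, entries: Iterable[tuple[str, int]]):
        self._names: list[str] = []
        self._lengths: dict[str, int] = {}
        for name, length in entries:
            if not name:
                raise InvalidParameterError("chromosome name is empty")
            if name in self._lengths:
                raise InvalidParameterError(f"duplicate chromosome name {name!r}")
            length = int(length)
            if length <= 0:
                raise InvalidParameterError(
                    f"chromosome {name!r} has non-positive length {length}"
                )
            self._names.append(name)
            self._lengths[name] = length
        if not self._names:
            raise InvalidParameterError("chromosome table is empty")
        self._rank = {name: i for i, name in enumerate(self._names)}

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def __len__(self) -> int:
        return len(self._names)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter((n, self._lengths[n]) for n in self._names)

    def __contains__(self, name: object) -> bool:
        return name in self._lengths

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChromTable):
            return NotImplemented
        return self._names == other._names and self._lengths == other._lengths

    def length(self, name: str) -> int:
        try:
            return self._lengths[name]
        except KeyError:
            raise NotFoundError(f"unknown chromosome {name!r}") from None

    def rank(self, name: str) -> int:
        try:
            return self._rank[name]
        except KeyError:
            raise NotFoundError(f"unknown chromosome {name!r}") from None

    def resolve_name(self, name: str) -> str:
        """Match a chromosome name exactly, then with/without a 'chr' prefix."""
        if name in self._lengths:
            return name
        alt = name[3:] if name.startswith("chr") else "chr" + name
        if alt in self._lengths:
            return alt
        raise NotFoundError(f"unknown chromosome {name!r}")

    def order_pair(self, a: str, b: str) -> tuple[str, str]:
        """Return (a, b) ordered by canonical rank (lower rank first)."""
        return (a, b) if self.rank(a) <= self.rank(b) else (b, a)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self:
                fh.write(f"{name}\t{length}\n")


def read_chrom_sizes(path: str | Path) -> ChromTable:
    """Read a two-column tab-delimited chrom.sizes file."""
    entries: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise QueryParseError(
                    f"{path}:{lineno}: expected 'name<TAB>length', got {line!r}"
                )
            entries.append((fields[0], int(fields[1])))
    return ChromTable(entries)


class BinIndex:
    """Fixed-width binning of a genome at one resolution.

    Bin ``i`` of a chromosome covers ``[i*resolution, min((i+1)*resolution,
    length))``; the last bin may be short.  Bin counts follow the ceiling rule
    ``n_c = ceil(length / resolution)``.
    """

    def __init__(self, chroms: ChromTable, resolution: int):
        if resolution <= 0:
            raise InvalidParameterError(f"resolution must be > 0, got {resolution}")
        self.chroms = chroms
        self.resolution = int(resolution)
        self.bin_counts: dict[str, int] = {
            name: -(-length // self.resolution) for name, length in chroms
        }

    @property
    def total_bins(self) -> int:
        return sum(self.bin_counts.values())

    def n_bins(self, chrom: str) -> int:
        try:
            return self.bin_counts[chrom]
        except KeyError:
            raise NotFoundError(f"unknown chromosome {chrom!r}") from None

    def bin_of(self, chrom: str, pos: int) -> int:
        if not 0 <= pos < self.chroms.length(chrom):
            raise InvalidParameterError(
                f"position {pos} outside {chrom} (length {self.chroms.length(chrom)})"
            )
        return pos // self.resolution

    def bin_bounds(self, chrom: str, i: int) -> tuple[int, int]:
        n = self.n_bins(chrom)
        if not 0 <= i < n:
            raise InvalidParameterError(f"bin {i} outside {chrom} (0..{n - 1})")
        start = i * self.resolution
        return start, min(start + self.resolution, self.chroms.length(chrom))

    def bin_span(self, interval: GenomicInterval) -> tuple[int, int]:
        """Half-open bin range covering an interval (clipped to the chromosome)."""
        chrom = self.chroms.resolve_name(interval.chrom)
        n = self.n_bins(chrom)
        b0 = min(interval.start // self.resolution, n)
        b1 = min(math.ceil(interval.end / self.resolution), n)
        return b0, max(b0, b1)


def make_bin_index(chroms: ChromTable, resolution: int) -> BinIndex:
    """Bin a genome at a fixed resolution (ceiling rule per chromosome)."""
    return BinIndex(chroms, resolution)


class AnnotationTable:
    """Feature id (gene symbol / RefSeq / Ensembl / rsid) -> interval lookup.

    Lookup is case-preserving with a case-insensitive fallback; the table is
    expected to be pre-deduplicated (one interval per id).
    """

    def __init__(self, records: Mapping[str, GenomicInterval] | Iterable[tuple[str, GenomicInterval]] = ()):
        items = records.items() if isinstance(records, Mapping) else records
        self._records: dict[str, GenomicInterval] = {}
        self._folded: dict[str, str] = {}
        for fid, iv in items:
            self.add(fid, iv)

    def add(self, fid: str, interval: GenomicInterval) -> None:
        if not fid:
            raise InvalidParameterError("feature id is empty")
        if fid in self._records:
            raise InvalidParameterError(f"duplicate feature id {fid!r}")
        self._records[fid] = interval
        self._folded.setdefault(fid.casefold(), fid)

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, fid: str) -> bool:
        return fid in self._records or fid.casefold() in self._folded

    def lookup(self, fid: str) -> GenomicInterval:
        if fid in self._records:
            return self._records[fid]
        key = self._folded.get(fid.casefold())
        if key is not None:
            return self._records[key]
        raise NotFoundError(f"feature id {fid!r} not in annotation table")


def read_annotation_bed(path: str | Path, chroms: ChromTable | None = None) -> AnnotationTable:
    """Read a BED4-like annotation table (chrom, start, end, id; 0-based half-open)."""
    table = AnnotationTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise QueryParseError(
                    f"{path}:{lineno}: expected >= 4 BED columns, got {len(fields)}"
                )
            chrom, start, end, fid = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if chroms is not None:
                chrom = chroms.resolve_name(chrom)
            table.add(fid, GenomicInterval(chrom, start, end))
    return table


_REGION_RE = re.compile(r"^\s*([^\s:]+)\s*:\s*([\d,]+)\s*-\s*([\d,]+)\s*$")


def _looks_like_region(q: str) -> bool:
    return _REGION_RE.match(q) is not None


def resolve_query(
    q: str,
    ann: AnnotationTable | None = None,
    chroms: ChromTable | None = None,
) -> GenomicInterval:
    """Resolve a query string to a validated genomic interval.

    Accepts coordinate strings (``chrom:start-end``, 0-based half-open,
    thousands separators tolerated) or any feature id present in ``ann``.
    Intervals running past the chromosome end are clipped with a warning.
    """
    q = q.strip()
    m = _REGION_RE.match(q)
    if m:
        chrom, start_s, end_s = m.groups()
        start = int(start_s.replace(",", ""))
        end = int(end_s.replace(",", ""))
        if start >= end:
            raise QueryParseError(f"malformed region {q!r}: start >= end")
        if chroms is not None:
            chrom = chroms.resolve_name(chrom)
            clen = chroms.length(chrom)
            if start >= clen:
                raise QueryParseError(
                    f"region {q!r} starts beyond end of {chrom} (length {clen})"
                )
            if end > clen:
                warnings.warn(
                    f"region {q!r} clipped to end of {chrom} ({clen})", stacklevel=2
                )
                end = clen
        return GenomicInterval(chrom, start, end)
    if ann is None:
        raise NotFoundError(
            f"{q!r} is not a coordinate string and no annotation table was given"
        )
    iv = ann.lookup(q)
    if chroms is not None:
        chrom = chroms.resolve_name(iv.chrom)
        clen = chroms.length(chrom)
        if iv.start >= clen:
            raise QueryParseError(
                f"annotation for {q!r} starts beyond end of {chrom} (length {clen})"
            )
        if iv.end > clen:
            warnings.warn(f"annotation for {q!r} clipped to end of {chrom}", stacklevel=2)
            iv = GenomicInterval(chrom, iv.start, clen)
        elif chrom != iv.chrom:
            iv = GenomicInterval(chrom, iv.start, iv.end)
    return iv


def render_region(interval: GenomicInterval) -> str:
    """Render an interval as a region string that resolve_query parses back."""
    return f"{interval.chrom}:{interval.start}-{interval.end}"
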