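"""Contact matrices: construction from read pairs, ICE balancing, virtual 4C.

A :class:`ContactMatrix` stores intra-chromosomal data as the upper triangle
of a sparse matrix (entry (i, j) with i <= j) and inter-chromosomal data as a
full sparse rectangle whose rows belong to the chromosome earlier in the
canonical chromosome order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import (
    DegenerateInputError,
    EncodingError,
    InvalidParameterError,
    NotFoundError,
    QueryParseError,
)
from .genome import BinIndex, ChromTable, GenomicInterval, make_bin_index

logger = logging.getLogger(__name__)

__all__ = [
    "ContactMatrix",
    "BiasVector",
    "VirtualTrack",
    "RejectReport",
    "bin_pairs",
    "ice_normalize",
    "virtual_4c",
    "export_bedgraph",
    "read_bedgraph",
    "read_matrix_text",
    "write_matrix_text",
]

#: relative tolerance beyond which (i, j)/(j, i) duplicates are a hard error
SYMMETRY_RTOL = 1e-5


class ContactMatrix:
    """Sparse contact matrix between fixed-width genomic bins.

    Parameters
    ----------
    chrom_a, chrom_b:
        Row and column chromosome names; equal for intra-chromosomal data.
    resolution:
        Bin width in base pairs.
    n_rows, n_cols:
        Bin counts along each axis (equal for intra).
    data:
        Sparse matrix of non-negative finite values; for intra matrices only
        the upper triangle (col >= row) may be populated.
    normalization:
        Free-text label of the value scale ("raw", "ICE", ...).
    """

    def __init__(
        self,
        chrom_a: str,
        chrom_b: str,
        resolution: int,
        n_rows: int,
        n_cols: int,
        data: sp.spmatrix,
        normalization: str = "raw",
    ):
        if resolution <= 0:
            raise InvalidParameterError(f"resolution must be > 0, got {resolution}")
        if n_rows <= 0 or n_cols <= 0:
            raise InvalidParameterError("matrix dimensions must be positive")
        intra = chrom_a == chrom_b
        if intra and n_rows != n_cols:
            raise InvalidParameterError("intra matrix must be square")
        data = sp.csr_matrix(data, shape=(n_rows, n_cols), dtype=np.float64)
        data.sum_duplicates()
        data.eliminate_zeros()
        if data.nnz:
            if not np.all(np.isfinite(data.data)):
                raise InvalidParameterError("matrix values must be finite")
            if np.any(data.data < 0):
                raise InvalidParameterError("matrix values must be >= 0")
        if intra and data.nnz:
            coo = data.tocoo()
            if np.any(coo.col < coo.row):
                raise InvalidParameterError(
                    "intra matrix must be upper triangular (col >= row)"
                )
        self.chrom_a = chrom_a
        self.chrom_b = chrom_b
        self.resolution = int(resolution)
        self.n_rows = int(n_rows)
        self.n_cols = int(n_cols)
        self.data = data
        self.normalization = normalization

    # ------------------------------------------------------------------
    @property
    def is_intra(self) -> bool:
        return self.chrom_a == self.chrom_b

    @property
    def kind(self) -> str:
        return "intra" if self.is_intra else "inter"

    @property
    def key(self) -> str | tuple[str, str]:
        return self.chrom_a if self.is_intra else (self.chrom_a, self.chrom_b)

    @property
    def nnz(self) -> int:
        return self.data.nnz

    def sum(self) -> float:
        """Total signal over the full (symmetrised, for intra) matrix."""
        if not self.is_intra:
            return float(self.data.sum())
        diag = self.data.diagonal().sum()
        return float(2 * self.data.sum() - diag)

    def to_dense(self, symmetric: bool = True) -> np.ndarray:
        """Dense array; intra matrices are mirrored to full symmetry by default."""
        dense = self.data.toarray()
        if self.is_intra and symmetric:
            dense = dense + dense.T - np.diag(np.diag(dense))
        return dense

    def with_data(self, data: sp.spmatrix, normalization: str | None = None) -> "ContactMatrix":
        return ContactMatrix(
            self.chrom_a,
            self.chrom_b,
            self.resolution,
            self.n_rows,
            self.n_cols,
            data,
            self.normalization if normalization is None else normalization,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContactMatrix):
            return NotImplemented
        return (
            self.key == other.key
            and self.resolution == other.resolution
            and (self.n_rows, self.n_cols) == (other.n_rows, other.n_cols)
            and (self.data != other.data).nnz == 0
        )

    def __repr__(self) -> str:
        return (
            f"<ContactMatrix {self.kind} {self.chrom_a}"
            + ("" if self.is_intra else f"x{self.chrom_b}")
            + f" {self.n_rows}x{self.n_cols} @ {self.resolution} bp,"
            f" nnz={self.nnz}, {self.normalization}>"
        )

    # ------------------------------------------------------------------
    @classmethod
    def from_coo(
        cls,
        chrom_a: str,
        chrom_b: str,
        resolution: int,
        n_rows: int,
        n_cols: int,
        rows: Sequence[int] | np.ndarray,
        cols: Sequence[int] | np.ndarray,
        vals: Sequence[float] | np.ndarray,
        normalization: str = "raw",
        accumulate: bool = False,
    ) -> "ContactMatrix":
        """Build from triples, folding intra entries to the upper triangle.

        With ``accumulate=False`` (matrix semantics) an entry listed both as
        (i, j) and (j, i) must agree within ``SYMMETRY_RTOL`` and is stored
        once; disagreement is an :class:`EncodingError`.  With
        ``accumulate=True`` (count semantics, as when binning read pairs) all
        duplicates are summed.
        """
        rows = np.asarray(rows, dtype=np.int64)
        cols = np.asarray(cols, dtype=np.int64)
        vals = np.asarray(vals, dtype=np.float64)
        if not (len(rows) == len(cols) == len(vals)):
            raise InvalidParameterError("rows/cols/vals lengths differ")
        if chrom_a != chrom_b:
            data = sp.coo_matrix((vals, (rows, cols)), shape=(n_rows, n_cols))
            return cls(chrom_a, chrom_b, resolution, n_rows, n_cols, data, normalization)

        lower = rows > cols
        r = np.where(lower, cols, rows)
        c = np.where(lower, rows, cols)
        if accumulate:
            data = sp.coo_matrix((vals, (r, c)), shape=(n_rows, n_cols))
            return cls(chrom_a, chrom_b, resolution, n_rows, n_cols, data, normalization)

        upper = sp.coo_matrix(
            (vals[~lower], (r[~lower], c[~lower])), shape=(n_rows, n_cols)
        ).tocsr()
        low = sp.coo_matrix(
            (vals[lower], (r[lower], c[lower])), shape=(n_rows, n_cols)
        ).tocsr()
        if low.nnz:
            both = (upper != 0).multiply(low != 0)
            if both.nnz:
                diff = abs(upper - low).multiply(both)
                scale = abs(upper).multiply(both)
                bad = diff > scale.multiply(SYMMETRY_RTOL)
                if bad.nnz:
                    i, j = bad.nonzero()
                    raise EncodingError(
                        f"conflicting symmetric values at ({i[0]}, {j[0]}): "
                        f"{upper[i[0], j[0]]} vs {low[i[0], j[0]]}"
                    )
            # keep upper's value where both are present, take lower elsewhere
            data = upper + low - low.multiply(upper != 0)
        else:
            data = upper
        return cls(chrom_a, chrom_b, resolution, n_rows, n_cols, data, normalization)

    @classmethod
    def from_dense(
        cls,
        chrom_a: str,
        chrom_b: str,
        resolution: int,
        dense: np.ndarray,
        normalization: str = "raw",
    ) -> "ContactMatrix":
        """Build from a dense array; intra input may be full symmetric."""
        dense = np.asarray(dense, dtype=np.float64)
        if dense.ndim != 2:
            raise InvalidParameterError("dense input must be 2-D")
        n_rows, n_cols = dense.shape
        if chrom_a == chrom_b:
            if n_rows != n_cols:
                raise InvalidParameterError("intra matrix must be square")
            if not np.tril(dense, -1).any():  # already upper triangular
                return cls(chrom_a, chrom_b, resolution, n_rows, n_cols,
                           sp.csr_matrix(dense), normalization)
            asym = np.abs(dense - dense.T)
            tol = SYMMETRY_RTOL * np.maximum(np.abs(dense), np.abs(dense.T))
            if np.any(asym > tol):
                i, j = np.argwhere(asym > tol)[0]
                raise EncodingError(
                    f"conflicting symmetric values at ({i}, {j}): "
                    f"{dense[i, j]} vs {dense[j, i]}"
                )
            dense = np.triu(dense)
        return cls(chrom_a, chrom_b, resolution, n_rows, n_cols,
                   sp.csr_matrix(dense), normalization)


# ----------------------------------------------------------------------
# Matrix text I/O

def read_matrix_text(
    path: str | Path,
    chrom_a: str,
    resolution: int,
    chrom_b: str | None = None,
    n_rows: int | None = None,
    n_cols: int | None = None,
    chroms: ChromTable | None = None,
    normalization: str = "raw",
) -> ContactMatrix:
    """Read a contact matrix from text, auto-detecting the dialect.

    Two dialects are accepted: a dense tab-delimited square/rectangular matrix
    (optional leading header row and/or label column), and sparse triples
    ``binA<TAB>binB<TAB>value`` where bins are integer ids or ``chrom:start``
    labels.  Triples files are detected by having exactly three columns whose
    third field is numeric.
    """
    chrom_b = chrom_b or chrom_a
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise QueryParseError(f"{path}: empty matrix file")
    ncol_first = len(first.rstrip("\n").split("\t"))

    if chroms is not None:
        if n_rows is None:
            n_rows = make_bin_index(chroms, resolution).n_bins(chrom_a)
        if n_cols is None:
            n_cols = make_bin_index(chroms, resolution).n_bins(chrom_b)

    if ncol_first == 3:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["a", "b", "value"], dtype=str)
        rows = _parse_bin_labels(df["a"], chrom_a, resolution)
        cols = _parse_bin_labels(df["b"], chrom_b, resolution)
        vals = df["value"].astype(float).to_numpy()
        nr = n_rows if n_rows is not None else int(rows.max()) + 1
        nc = n_cols if n_cols is not None else int(cols.max()) + 1
        if chrom_a == chrom_b:
            nr = nc = max(nr, nc)
        return ContactMatrix.from_coo(
            chrom_a, chrom_b, resolution, nr, nc, rows, cols, vals,
            normalization=normalization,
        )

    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    # strip optional label header row / column
    def _is_num(s: object) -> bool:
        try:
            float(s)  # type: ignore[arg-type]
            return True
        except (TypeError, ValueError):
            return False

    if not _is_num(df.iloc[0, df.shape[1] - 1]):
        df = df.iloc[1:, :]
    if not _is_num(df.iloc[df.shape[0] - 1, 0]):
        df = df.iloc[:, 1:]
    dense = df.to_numpy(dtype=np.float64)
    return ContactMatrix.from_dense(chrom_a, chrom_b, resolution, dense,
                                    normalization=normalization)


def _parse_bin_labels(col: pd.Series, chrom: str, resolution: int) -> np.ndarray:
    sample = col.iloc[0]
    if ":" in sample:
        parts = col.str.split(":", expand=True)
        starts = parts[1].str.replace(",", "").astype(np.int64)
        return (starts // resolution).to_numpy()
    return col.astype(np.int64).to_numpy()


def write_matrix_text(m: ContactMatrix, path: str | Path, sparse: bool = False) -> None:
    """Write a matrix as dense TSV (full symmetric for intra) or sparse triples."""
    with open(path, "w") as fh:
        if sparse:
            coo = m.data.tocoo()
            order = np.lexsort((coo.col, coo.row))
            for r, c, v in zip(coo.row[order], coo.col[order], coo.data[order]):
                fh.write(f"{r}\t{c}\t{v:g}\n")
        else:
            dense = m.to_dense(symmetric=True)
            for row in dense:
                fh.write("\t".join(f"{v:g}" for v in row))
                fh.write("\n")


# ----------------------------------------------------------------------
# Pairs binning

@dataclass
class RejectReport:
    """Bookkeeping for :func:`bin_pairs`; retained + all rejects == total."""

    total: int = 0
    retained: int = 0
    low_mapq: int = 0
    unknown_chrom: int = 0
    out_of_range: int = 0
    inter_dropped: int = 0

    def rejected(self) -> int:
        return self.low_mapq + self.unknown_chrom + self.out_of_range + self.inter_dropped

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("category\tcount\n")
            for name in ("total", "retained", "low_mapq", "unknown_chrom",
                         "out_of_range", "inter_dropped"):
                fh.write(f"{name}\t{getattr(self, name)}\n")


#: pairs dialect: readID chrom1 pos1 chrom2 pos2 [strand1 strand2 [mapq1 mapq2]]
_PAIRS_BASE_COLS = ["read_id", "chrom1", "pos1", "chrom2", "pos2"]


def bin_pairs(
    pairs: str | Path | Iterable[tuple],
    chroms: ChromTable,
    resolution: int,
    same_chrom_only: bool = True,
    mapq_min: int = 30,
) -> tuple[dict[str | tuple[str, str], ContactMatrix], RejectReport]:
    """Bin read pairs into contact matrices.

    Each retained pair increments one matrix cell; intra pairs are folded to
    the upper triangle.  With ``same_chrom_only`` (the usual Hi-C pipeline
    default) inter-chromosomal pairs are dropped and counted; with it off,
    inter matrices keyed by canonically ordered chromosome pairs are also
    produced.  Positions are 1-based 5' coordinates as in .pairs text.
    The mapq filter applies only when the file carries mapq columns.
    """
    index = make_bin_index(chroms, resolution)
    if isinstance(pairs, (str, Path)):
        df = _read_pairs_file(pairs)
    else:
        rows = list(pairs)
        cols = _PAIRS_BASE_COLS + ["mapq1", "mapq2"][: max(0, (len(rows[0]) - 5) if rows else 0)]
        df = pd.DataFrame(rows, columns=cols[: len(rows[0])] if rows else _PAIRS_BASE_COLS)

    report = RejectReport(total=len(df))
    empty_keys: dict[str | tuple[str, str], ContactMatrix] = {}
    if df.empty:
        return empty_keys, report

    keep = np.ones(len(df), dtype=bool)
    if "mapq1" in df.columns and "mapq2" in df.columns:
        mq_ok = (df["mapq1"].astype(int) >= mapq_min) & (df["mapq2"].astype(int) >= mapq_min)
        report.low_mapq = int((~mq_ok & keep).sum())
        keep &= mq_ok.to_numpy()

    # chromosome name resolution with 'chr' fallback, vectorised over uniques
    def _canonical(series: pd.Series) -> pd.Series:
        mapping = {}
        for name in series.unique():
            try:
                mapping[name] = chroms.resolve_name(str(name))
            except NotFoundError:
                mapping[name] = None
        return series.map(mapping)

    c1 = _canonical(df["chrom1"].astype(str))
    c2 = _canonical(df["chrom2"].astype(str))
    chrom_ok = c1.notna().to_numpy() & c2.notna().to_numpy()
    report.unknown_chrom = int((~chrom_ok & keep).sum())
    keep &= chrom_ok

    pos1 = df["pos1"].astype(np.int64).to_numpy()
    pos2 = df["pos2"].astype(np.int64).to_numpy()
    lengths = {name: length for name, length in chroms}
    len1 = c1.map(lengths).fillna(0).to_numpy(dtype=np.int64)
    len2 = c2.map(lengths).fillna(0).to_numpy(dtype=np.int64)
    pos_ok = (pos1 >= 1) & (pos1 <= len1) & (pos2 >= 1) & (pos2 <= len2)
    report.out_of_range = int((~pos_ok & keep).sum())
    keep &= pos_ok

    inter = (c1 != c2).to_numpy()
    if same_chrom_only:
        report.inter_dropped = int((inter & keep).sum())
        keep &= ~inter

    report.retained = int(keep.sum())
    c1k = c1.to_numpy()[keep]
    c2k = c2.to_numpy()[keep]
    b1 = (pos1[keep] - 1) // resolution
    b2 = (pos2[keep] - 1) // resolution

    matrices: dict[str | tuple[str, str], ContactMatrix] = {}
    df_bins = pd.DataFrame({"c1": c1k, "c2": c2k, "b1": b1, "b2": b2})
    for (ca, cb), grp in df_bins.groupby(["c1", "c2"], sort=False):
        rows_g = grp["b1"].to_numpy()
        cols_g = grp["b2"].to_numpy()
        if ca == cb:
            key: str | tuple[str, str] = ca
            _merge_counts(matrices, key, ca, cb, resolution,
                          index.n_bins(ca), index.n_bins(cb), rows_g, cols_g)
        else:
            oa, ob = chroms.order_pair(ca, cb)
            if (oa, ob) != (ca, cb):
                rows_g, cols_g = cols_g, rows_g
            _merge_counts(matrices, (oa, ob), oa, ob, resolution,
                          index.n_bins(oa), index.n_bins(ob), rows_g, cols_g)

    # guarantee an (all-zero) intra matrix per chromosome so empty input is explicit
    for name in chroms.names:
        if name not in matrices:
            matrices[name] = ContactMatrix(
                name, name, resolution, index.n_bins(name), index.n_bins(name),
                sp.csr_matrix((index.n_bins(name), index.n_bins(name))),
            )
    logger.info("bin_pairs: %d/%d pairs retained", report.retained, report.total)
    return matrices, report


def _merge_counts(matrices, key, ca, cb, resolution, nr, nc, rows, cols) -> None:
    m = ContactMatrix.from_coo(ca, cb, resolution, nr, nc, rows, cols,
                               np.ones(len(rows)), accumulate=True)
    if key in matrices:
        matrices[key] = matrices[key].with_data(matrices[key].data + m.data)
    else:
        matrices[key] = m


def _read_pairs_file(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=_PAIRS_BASE_COLS)
    if df.shape[1] < 5:
        raise QueryParseError(
            f"{path}: pairs text needs >= 5 columns (readID chrom1 pos1 chrom2 pos2)"
        )
    names = list(_PAIRS_BASE_COLS)
    extra = df.shape[1] - 5
    if extra >= 2:
        names += ["strand1", "strand2"]
    if extra >= 4:
        names += ["mapq1", "mapq2"]
    names += [f"extra{i}" for i in range(df.shape[1] - len(names))]
    df.columns = names
    return df


# ----------------------------------------------------------------------
# ICE balancing

@dataclass
class BiasVector:
    """Per-bin multiplicative biases from iterative correction.

    Unmasked biases are positive with unit geometric mean; masked
    (zero-coverage) bins carry NaN.
    """

    bias: np.ndarray
    mask: np.ndarray  # True where the bin is excluded
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.bias = np.asarray(self.bias, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)


def ice_normalize(
    m: ContactMatrix,
    tol: float = 1e-5,
    max_iter: int = 200,
) -> tuple[ContactMatrix, BiasVector]:
    """Iterative correction: equalise row sums by removing multiplicative bias.

    Repeatedly divides the symmetric matrix by the outer product of its
    normalised row sums until the sums are uniform to within ``tol``.  Bins
    with zero marginal are masked out before iterating.  The balanced matrix
    is rescaled so its total equals the input total; accumulated biases are
    returned with unit geometric mean.  Non-convergence within ``max_iter``
    sets ``converged=False`` (with a warning) rather than raising.
    """
    if not m.is_intra:
        raise InvalidParameterError("ICE applies to intra-chromosomal matrices")
    if tol <= 0:
        raise InvalidParameterError("tol must be > 0")
    dense = m.to_dense(symmetric=True)
    n = dense.shape[0]
    mask = dense.sum(axis=1) == 0
    if mask.all():
        raise DegenerateInputError("all bins have zero coverage")
    live = ~mask
    work = dense[np.ix_(live, live)].copy()
    bias_live = np.ones(work.shape[0])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        s = work.sum(axis=1)
        db = s / s.mean()
        if np.max(np.abs(db - 1)) < tol:
            converged = True
            break
        work /= np.outer(db, db)
        bias_live *= db
    if not converged:
        warnings.warn(
            f"ICE did not converge in {max_iter} iterations", stacklevel=2
        )

    total_in = dense[np.ix_(live, live)].sum()
    total_out = work.sum()
    if total_out > 0:
        c = total_in / total_out
        work *= c
        bias_live /= np.sqrt(c)
    # unit geometric mean convention
    gm = np.exp(np.mean(np.log(bias_live)))
    bias_live /= gm

    out = np.zeros_like(dense)
    out[np.ix_(live, live)] = work
    bias = np.full(n, np.nan)
    bias[live] = bias_live
    normalized = ContactMatrix.from_dense(
        m.chrom_a, m.chrom_b, m.resolution, out, normalization="ICE"
    )
    return normalized, BiasVector(bias=bias, mask=mask, converged=converged, n_iter=it)


# ----------------------------------------------------------------------
# Virtual 4C

@dataclass
class VirtualTrack:
    """One-vs-many interaction profile of a bait locus across a window."""

    bait: GenomicInterval
    window: GenomicInterval
    resolution: int
    signal: np.ndarray
    bin_starts: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    bin_ends: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.bin_starts is None:
            b0 = self.window.start // self.resolution
            starts = (b0 + np.arange(len(self.signal))) * self.resolution
            self.bin_starts = starts
            self.bin_ends = np.minimum(starts + self.resolution, self.window.end)


def virtual_4c(
    source,
    bait: GenomicInterval,
    window: GenomicInterval,
    smooth_bins: int = 1,
) -> VirtualTrack:
    """Extract a virtual-4C profile: mean contact of the bait bins per window bin.

    ``source`` is a :class:`ContactMatrix` or any object with a
    ``query(a, b)`` method returning a dense rectangle (e.g. an open BUTLR
    file).  With a single-bin bait and ``smooth_bins=1`` the signal equals the
    corresponding matrix row restricted to the window.
    """
    if smooth_bins < 1 or smooth_bins % 2 == 0:
        raise InvalidParameterError("smooth_bins must be odd and >= 1")
    if bait.chrom != window.chrom:
        raise InvalidParameterError("bait and window must share a chromosome")
    if not (window.start <= bait.start and bait.end <= window.end):
        raise InvalidParameterError("bait must lie within the window")

    if isinstance(source, ContactMatrix):
        if bait.chrom not in (source.chrom_a, source.chrom_b):
            raise NotFoundError(f"chromosome {bait.chrom!r} absent from matrix")
        if not source.is_intra:
            raise InvalidParameterError("virtual 4C needs an intra-chromosomal source")
        res = source.resolution
        n = source.n_rows
        dense = source.to_dense(symmetric=True)
        bb0, bb1 = bait.start // res, min(-(-bait.end // res), n)
        wb0, wb1 = window.start // res, min(-(-window.end // res), n)
        sub = dense[bb0:bb1, wb0:wb1]
    else:
        res = source.resolution
        sub = source.query(bait, window)
        wb0 = window.start // res
        wb1 = wb0 + sub.shape[1]

    signal = sub.mean(axis=0)
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins)
        signal = np.convolve(signal, kernel, mode="same") / np.convolve(
            np.ones_like(signal), kernel, mode="same"
        )
    starts = (wb0 + np.arange(len(signal))) * res
    ends = np.minimum(starts + res, window.end if window.end > starts[-1] else starts[-1] + res)
    return VirtualTrack(bait=bait, window=window, resolution=res, signal=signal,
                        bin_starts=starts, bin_ends=ends)


def export_bedgraph(t: VirtualTrack, destination: str | Path) -> None:
    """Write a track as bedGraph (0-based half-open); zeros are kept explicit."""
    with open(destination, "w") as fh:
        for s, e, v in zip(t.bin_starts, t.bin_ends, t.signal):
            fh.write(f"{t.window.chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph file into columns (chrom, start, end, value)."""
    return pd.read_csv(path, sep="\t", header=None, comment="#",
                       names=["chrom", "start", "end", "value"])
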