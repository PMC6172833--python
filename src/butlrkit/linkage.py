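"""DHS-linkage: pair proximal and distal open-chromatin sites by correlation.

Promoter-proximal and distal DNase hypersensitive sites are linked when their
accessibility profiles across a panel of cell types correlate strongly
(Pearson r strictly greater than a threshold, 0.7 by default) and the sites
are near each other (midpoint distance at most 500 kb by default).  Distance
is midpoint-to-midpoint, which is symmetric and order-free.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .genome import GenomicInterval

logger = logging.getLogger(__name__)

__all__ = ["DhsSite", "dhs_linkage", "read_dhs_table", "write_dhs_table"]

DEFAULT_PCC_MIN = 0.7
DEFAULT_MAX_DIST = 500_000


@dataclass
class DhsSite:
    """One DNase-hypersensitive site with its cross-cell-type signal vector."""

    interval: GenomicInterval
    role: str  # "proximal" | "distal"
    signal: np.ndarray
    site_id: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("proximal", "distal"):
            raise InvalidParameterError(f"unknown DHS role {self.role!r}")
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if not np.all(np.isfinite(self.signal)):
            raise InvalidParameterError(f"site {self.site_id or self.interval}: non-finite signal")


def _signal_matrix(sites: Sequence[DhsSite]) -> np.ndarray:
    lengths = {len(s.signal) for s in sites}
    if len(lengths) > 1:
        raise InvalidParameterError("signal vectors differ in length across sites")
    return np.vstack([s.signal for s in sites])


def dhs_linkage(
    proximal: Sequence[DhsSite],
    distal: Sequence[DhsSite],
    pcc_min: float = DEFAULT_PCC_MIN,
    max_dist: int = DEFAULT_MAX_DIST,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Return linked proximal-distal pairs as a BEDPE-like table.

    Every same-chromosome pair with midpoint distance <= ``max_dist`` is
    evaluated; pairs are kept when their Pearson correlation is strictly
    greater than ``pcc_min``.  Zero-variance signal vectors make the
    correlation undefined; such pairs are skipped with a warning.  The output
    is sorted by proximal start position, then by descending correlation.

    The correlation is computed as cov / sqrt(var_p * var_d) with population
    moments, which keeps exactly representable inputs exact.
    """
    columns = [
        "chrom", "start_p", "end_p", "id_p",
        "start_d", "end_d", "id_d", "distance", "pcc",
    ]
    if not proximal or not distal:
        return pd.DataFrame(columns=columns)

    sig_p = _signal_matrix(proximal)
    sig_d = _signal_matrix(distal)
    if sig_p.shape[1] != sig_d.shape[1]:
        raise InvalidParameterError("proximal and distal signal lengths differ")
    k = sig_p.shape[1]
    if k < 3:
        raise InvalidParameterError(f"need >= 3 cell types, got {k}")
    if log_transform:
        if np.any(sig_p < 0) or np.any(sig_d < 0):
            raise InvalidParameterError("log transform requires non-negative signal")
        sig_p = np.log1p(sig_p)
        sig_d = np.log1p(sig_d)

    cp = sig_p - sig_p.mean(axis=1, keepdims=True)
    cd = sig_d - sig_d.mean(axis=1, keepdims=True)
    var_p = (cp ** 2).mean(axis=1)
    var_d = (cd ** 2).mean(axis=1)
    cov = (cp @ cd.T) / k
    with np.errstate(divide="ignore", invalid="ignore"):
        pcc = cov / np.sqrt(np.outer(var_p, var_d))

    mid_p = np.array([s.interval.midpoint for s in proximal])
    mid_d = np.array([s.interval.midpoint for s in distal])
    chrom_p = np.array([s.interval.chrom for s in proximal])
    chrom_d = np.array([s.interval.chrom for s in distal])
    dist = np.abs(mid_p[:, None] - mid_d[None, :])
    same_chrom = chrom_p[:, None] == chrom_d[None, :]
    candidate = same_chrom & (dist <= max_dist)

    degenerate = (var_p[:, None] == 0) | (var_d[None, :] == 0)
    n_skip = int((candidate & degenerate).sum())
    if n_skip:
        warnings.warn(
            f"{n_skip} candidate pair(s) skipped: zero-variance signal makes "
            "the correlation undefined", stacklevel=2,
        )
    keep = candidate & ~degenerate & (pcc > pcc_min)

    ip, idx = np.nonzero(keep)
    records = []
    for i, j in zip(ip, idx):
        p, d = proximal[i], distal[j]
        records.append((
            p.interval.chrom, p.interval.start, p.interval.end,
            p.site_id or f"proximal_{i}",
            d.interval.start, d.interval.end, d.site_id or f"distal_{j}",
            float(dist[i, j]), float(pcc[i, j]),
        ))
    df = pd.DataFrame(records, columns=columns)
    df = df.sort_values(["start_p", "pcc"], ascending=[True, False], kind="stable")
    df = df.reset_index(drop=True)
    logger.info("dhs_linkage: kept %d of %d candidate pairs", len(df), int(candidate.sum()))
    return df


def read_dhs_table(path: str | Path) -> tuple[list[DhsSite], list[DhsSite]]:
    """Read a site table (chrom, start, end, role, v1..vK) into (proximal, distal)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 7:
        raise InvalidParameterError(
            "DHS table needs chrom, start, end, role and >= 3 signal columns"
        )
    proximal: list[DhsSite] = []
    distal: list[DhsSite] = []
    for i, row in enumerate(df.itertuples(index=False)):
        role = str(row[3])
        site = DhsSite(
            interval=GenomicInterval(str(row[0]), int(row[1]), int(row[2])),
            role=role,
            signal=np.asarray(row[4:], dtype=np.float64),
            site_id=f"{role}_{i}",
        )
        (proximal if role == "proximal" else distal).append(site)
    return proximal, distal


def write_dhs_table(sites: Sequence[DhsSite], path: str | Path) -> None:
    """Write sites in the table dialect read_dhs_table expects."""
    with open(path, "w") as fh:
        for s in sites:
            vals = "\t".join(f"{v:.6g}" for v in s.signal)
            fh.write(f"{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}"
                     f"\t{s.role}\t{vals}\n")
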