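"""Seeded generators for every input the other modules consume.

The generators emulate the statistical shape of mammalian Hi-C data — a
power-law decay of contact frequency with genomic distance, multiplicative
per-bin biases, block-enriched self-interacting domains, inter-chromosomal
translocation blocks — and of cross-cell-type DNase accessibility panels.
Every generator is a pure function of (parameters, seed): the recorded
:class:`SimTruth` plus the seed regenerate the dataset bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .errors import InvalidParameterError
from .genome import ChromTable, GenomicInterval, make_bin_index
from .linkage import DhsSite
from .matrix import ContactMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimTruth",
    "random_boundaries",
    "simulate_hic",
    "simulate_pairs",
    "simulate_translocation",
    "simulate_dhs_table",
    "random_sparse_matrix",
]

#: contact-frequency decay exponent, typical of the Hi-C distance regime
DEFAULT_ALPHA = 1.0
#: within-domain contact enrichment over the background decay
DEFAULT_TAU = 3.0


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset (with its seed, fully determining it)."""

    seed: int
    resolution: int | None = None
    alpha: float | None = None
    tau: float | None = None
    depth: int | None = None
    tad_boundaries: dict[str, list[int]] = field(default_factory=dict)
    bias: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    inter_fraction: float | None = None
    n_inter_pairs: int | None = None
    linked_pairs: list[tuple[str, str]] = field(default_factory=list)
    breakpoints: tuple[tuple[str, int], tuple[str, int]] | None = None
    reciprocal: bool | None = None
    rho: float | None = None
    matrices: dict = field(default_factory=dict, repr=False)


def random_boundaries(n_bins: int, k: int, min_gap: int = 5,
                      rng: np.random.Generator | None = None,
                      seed: int | None = None) -> list[int]:
    """Draw k sorted domain-start bins with pairwise (and edge) gaps >= min_gap."""
    if rng is None:
        rng = np.random.default_rng(seed)
    slack = n_bins - (k + 1) * min_gap
    if k < 0 or slack < 0:
        raise InvalidParameterError(
            f"cannot place {k} boundaries with gap {min_gap} in {n_bins} bins"
        )
    picks = np.sort(rng.choice(slack + 1, size=k, replace=True))
    return [int(p + (i + 1) * min_gap) for i, p in enumerate(picks)]


def _domain_ids(n: int, boundaries: list[int]) -> np.ndarray:
    ids = np.zeros(n, dtype=np.int64)
    for b in boundaries:
        if not 0 < b < n:
            raise InvalidParameterError(f"boundary bin {b} outside (0, {n})")
        ids[b:] += 1
    if sorted(boundaries) != list(boundaries):
        raise InvalidParameterError("boundaries must be sorted")
    return ids


def _intensity(n: int, boundaries: list[int], alpha: float, tau: float,
               bias: np.ndarray | None) -> np.ndarray:
    """Expected full symmetric intensity: b_i b_j (1+|i-j|)^-alpha * enrichment."""
    idx = np.arange(n)
    lam = (1.0 + np.abs(idx[:, None] - idx[None, :])) ** (-alpha)
    dom = _domain_ids(n, boundaries)
    lam *= np.where(dom[:, None] == dom[None, :], tau, 1.0)
    if bias is not None:
        bias = np.asarray(bias, dtype=np.float64)
        if bias.shape != (n,) or np.any(bias <= 0):
            raise InvalidParameterError("bias must be a positive vector of length n_bins")
        lam *= np.outer(bias, bias)
    return lam


def simulate_hic(
    chroms: ChromTable,
    resolution: int,
    tad_boundaries: dict[str, list[int]] | None = None,
    alpha: float = DEFAULT_ALPHA,
    tau: float = DEFAULT_TAU,
    bias: dict[str, np.ndarray] | None = None,
    depth: int = 1_000_000,
    seed: int = 0,
) -> tuple[dict[str, ContactMatrix], SimTruth]:
    """Simulate TAD-structured intra-chromosomal contact matrices.

    Cell (i, j) is Poisson with mean proportional to
    ``b_i * b_j * (1 + |i - j|)**(-alpha)``, multiplied by ``tau`` when i and
    j fall in the same planted domain.  ``depth`` read pairs are spread over
    chromosomes proportionally to their squared bin counts; counts are drawn
    on the upper triangle and the matrix is symmetric by construction.
    """
    if depth <= 0:
        raise InvalidParameterError("depth must be > 0")
    rng = np.random.default_rng(seed)
    index = make_bin_index(chroms, resolution)
    tad_boundaries = tad_boundaries or {}
    bias = bias or {}
    weights = {name: index.n_bins(name) ** 2 for name in chroms.names}
    wtotal = sum(weights.values())
    matrices: dict[str, ContactMatrix] = {}
    for name in chroms.names:
        n = index.n_bins(name)
        lam = _intensity(n, tad_boundaries.get(name, []), alpha, tau, bias.get(name))
        upper = np.triu(lam)
        chrom_depth = depth * weights[name] / wtotal
        upper *= chrom_depth / upper.sum()
        counts = rng.poisson(upper).astype(np.float64)
        matrices[name] = ContactMatrix(name, name, resolution, n, n,
                                       sp.csr_matrix(counts))
    truth = SimTruth(seed=seed, resolution=resolution, alpha=alpha, tau=tau,
                     depth=depth,
                     tad_boundaries={c: list(v) for c, v in tad_boundaries.items()},
                     bias={c: np.asarray(v, float) for c, v in bias.items()},
                     matrices=matrices)
    return matrices, truth


def simulate_pairs(
    chroms: ChromTable,
    resolution: int,
    destination: str | Path,
    tad_boundaries: dict[str, list[int]] | None = None,
    alpha: float = DEFAULT_ALPHA,
    tau: float = DEFAULT_TAU,
    bias: dict[str, np.ndarray] | None = None,
    depth: int = 1_000_000,
    inter_fraction: float = 0.0,
    seed: int = 0,
) -> SimTruth:
    """Write a read-pairs text file whose binned matrix is known exactly.

    Intra pairs are drawn from :func:`simulate_hic`; each simulated count is
    emitted as one read pair with 1-based positions uniform inside its bins,
    with random mate order, so binning the file at the same resolution
    regenerates ``truth.matrices`` exactly.  A Binomial(depth, inter_fraction)
    number of inter-chromosomal pairs with uniform positions is mixed in to
    exercise the same-chromosome filter.
    """
    if not 0 <= inter_fraction <= 1:
        raise InvalidParameterError("inter_fraction must lie in [0, 1]")
    if depth < 0:
        raise InvalidParameterError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    lines: list[tuple[str, int, str, int]] = []
    truth = SimTruth(seed=seed, resolution=resolution, alpha=alpha, tau=tau,
                     depth=depth, inter_fraction=inter_fraction)
    if depth == 0:
        Path(destination).write_text(
            "## pairs format v1.0\n#columns: readID chrom1 pos1 chrom2 pos2 strand1 strand2\n"
        )
        truth.n_inter_pairs = 0
        return truth

    n_inter = int(rng.binomial(depth, inter_fraction)) if len(chroms) > 1 else 0
    n_intra = depth - n_inter
    truth.n_inter_pairs = n_inter

    if n_intra > 0:
        matrices, hic_truth = simulate_hic(
            chroms, resolution, tad_boundaries, alpha, tau, bias,
            depth=n_intra, seed=int(rng.integers(0, 2**31 - 1)),
        )
        truth.tad_boundaries = hic_truth.tad_boundaries
        truth.bias = hic_truth.bias
        truth.matrices = matrices
        for name, m in matrices.items():
            length = chroms.length(name)
            coo = m.data.tocoo()
            counts = coo.data.astype(np.int64)
            r = np.repeat(coo.row, counts)
            c = np.repeat(coo.col, counts)
            p1 = rng.integers(r * resolution + 1,
                              np.minimum((r + 1) * resolution, length) + 1)
            p2 = rng.integers(c * resolution + 1,
                              np.minimum((c + 1) * resolution, length) + 1)
            swap = rng.random(len(r)) < 0.5
            a1 = np.where(swap, p2, p1)
            a2 = np.where(swap, p1, p2)
            lines.extend((name, int(x), name, int(y)) for x, y in zip(a1, a2))

    names = chroms.names
    for _ in range(n_inter):
        ia, ib = rng.choice(len(names), size=2, replace=False)
        ca, cb = names[ia], names[ib]
        lines.append((ca, int(rng.integers(1, chroms.length(ca) + 1)),
                      cb, int(rng.integers(1, chroms.length(cb) + 1))))

    order = rng.permutation(len(lines))
    with open(destination, "w") as fh:
        fh.write("## pairs format v1.0\n")
        fh.write("#columns: readID chrom1 pos1 chrom2 pos2 strand1 strand2\n")
        for k, i in enumerate(order):
            c1, p1, c2, p2 = lines[i]
            fh.write(f"sim{k}\t{c1}\t{p1}\t{c2}\t{p2}\t+\t-\n")
    logger.info("wrote %d pairs (%d inter) to %s", len(lines), n_inter, destination)
    return truth


def simulate_translocation(
    chroms: ChromTable,
    resolution: int,
    breakpoint_a: tuple[str, int],
    breakpoint_b: tuple[str, int],
    reciprocal: bool = False,
    depth: int = 500_000,
    intensity: float = 0.3,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
) -> tuple[ContactMatrix, SimTruth]:
    """Simulate the inter-chromosomal signature of a translocation.

    The matrix is uniform background noise plus a decay-shaped block anchored
    at the two breakpoints: on the derivative chromosome, loci at distances
    da and db from the fusion junction are (da + db) apart, so enrichment
    falls off as ``(1 + da + db)**(-alpha)`` into the quadrant joined by the
    fusion.  ``reciprocal`` adds the mirrored quadrant, as when both
    derivative chromosomes are retained.  ``intensity`` is the expected
    fraction of reads coming from the fusion; 0 gives pure background.
    """
    if depth <= 0:
        raise InvalidParameterError("depth must be > 0")
    if not 0 <= intensity <= 1:
        raise InvalidParameterError("intensity must lie in [0, 1]")
    ca, pa = breakpoint_a
    cb, pb = breakpoint_b
    ca, cb = chroms.resolve_name(ca), chroms.resolve_name(cb)
    if ca == cb:
        raise InvalidParameterError("translocation breakpoints must be on different chromosomes")
    if not (0 <= pa < chroms.length(ca)) or not (0 <= pb < chroms.length(cb)):
        raise InvalidParameterError("breakpoint outside its chromosome")
    if chroms.rank(ca) > chroms.rank(cb):
        ca, cb, pa, pb = cb, ca, pb, pa
    index = make_bin_index(chroms, resolution)
    nr, nc = index.n_bins(ca), index.n_bins(cb)
    ba, bb = pa // resolution, pb // resolution

    rng = np.random.default_rng(seed)
    lam = np.full((nr, nc), (1.0 - intensity) * depth / (nr * nc))
    if intensity > 0:
        i = np.arange(nr)[:, None]
        j = np.arange(nc)[None, :]
        d1 = np.maximum(1.0 + (ba - i) + (j - bb), 1.0)
        q1 = np.where((i <= ba) & (j >= bb), d1 ** (-alpha), 0.0)
        quadrants = [q1]
        if reciprocal:
            d2 = np.maximum(1.0 + (i - ba) + (bb - j), 1.0)
            q2 = np.where((i >= ba) & (j <= bb), d2 ** (-alpha), 0.0)
            quadrants.append(q2)
        share = intensity * depth / len(quadrants)
        for q in quadrants:
            lam += q * (share / q.sum())
    counts = rng.poisson(lam).astype(np.float64)
    m = ContactMatrix(ca, cb, resolution, nr, nc, sp.csr_matrix(counts))
    truth = SimTruth(seed=seed, resolution=resolution, alpha=alpha, depth=depth,
                     breakpoints=((ca, pa), (cb, pb)), reciprocal=reciprocal)
    return m, truth


def simulate_dhs_table(
    n_prox: int = 50,
    n_dist: int = 200,
    n_celltypes: int = 120,
    linked_fraction: float = 0.25,
    rho: float = 0.9,
    chrom: str = "chr1",
    site_width: int = 200,
    prox_spacing: int = 1_000_000,
    seed: int = 0,
) -> tuple[list[DhsSite], list[DhsSite], SimTruth]:
    """Simulate a DHS site panel with planted proximal-distal linkages.

    Each proximal site carries a latent cell-type profile; a linked distal
    site mixes the same latent with noise so the expected Pearson correlation
    is ``rho``, and sits within 500 kb of its partner.  Unlinked distal sites
    have independent profiles and uniform positions.  Signals are standardised
    accessibility scores (zero mean, unit variance across sites).
    """
    if n_celltypes < 3:
        raise InvalidParameterError("need >= 3 cell types")
    if not 0 <= linked_fraction <= 1:
        raise InvalidParameterError("linked_fraction must lie in [0, 1]")
    if not -1 <= rho <= 1:
        raise InvalidParameterError("|rho| must be <= 1")
    rng = np.random.default_rng(seed)
    span = (n_prox + 1) * prox_spacing

    latent = rng.standard_normal((n_prox, n_celltypes))
    a = np.sqrt(abs(rho))
    b = np.sqrt(1 - abs(rho))
    sgn = np.sign(rho) if rho != 0 else 1.0

    proximal: list[DhsSite] = []
    for i in range(n_prox):
        signal = a * latent[i] + b * rng.standard_normal(n_celltypes)
        start = (i + 1) * prox_spacing
        proximal.append(DhsSite(GenomicInterval(chrom, start, start + site_width),
                                "proximal", signal, site_id=f"proximal_{i}"))

    n_linked = round(linked_fraction * n_dist)
    partners = rng.integers(0, n_prox, size=n_linked) if n_prox else np.array([], int)
    distal: list[DhsSite] = []
    linked_pairs: list[tuple[str, str]] = []
    for j in range(n_dist):
        if j < n_linked:
            p = int(partners[j])
            signal = sgn * a * latent[p] + b * rng.standard_normal(n_celltypes)
            offset = int(rng.integers(5_000, 450_000)) * (1 if rng.random() < 0.5 else -1)
            start = max(0, (p + 1) * prox_spacing + offset)
            linked_pairs.append((f"proximal_{p}", f"distal_{j}"))
        else:
            signal = rng.standard_normal(n_celltypes)
            start = int(rng.integers(0, span))
        distal.append(DhsSite(GenomicInterval(chrom, start, start + site_width),
                              "distal", signal, site_id=f"distal_{j}"))
    truth = SimTruth(seed=seed, rho=rho, linked_pairs=linked_pairs)
    return proximal, distal, truth


def random_sparse_matrix(
    n_rows: int,
    density: float,
    seed: int = 0,
    chrom_a: str = "chr1",
    chrom_b: str | None = None,
    n_cols: int | None = None,
    resolution: int = 10_000,
    max_value: int = 1000,
) -> ContactMatrix:
    """A random sparse matrix with integer values (exact under float32).

    Intra by default (upper-triangular occupancy at about ``density`` of the
    full square); pass a distinct ``chrom_b`` for a rectangular inter matrix.
    Used as a structureless fixture for format round-trip and query tests.
    """
    if not 0 < density <= 1:
        raise InvalidParameterError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    intra = chrom_b is None or chrom_b == chrom_a
    chrom_b = chrom_a if intra else chrom_b
    n_cols = n_rows if n_cols is None else n_cols
    target = max(1, int(round(density * n_rows * n_cols / (2 if intra else 1))))
    r = rng.integers(0, n_rows, size=2 * target + 8)
    c = rng.integers(0, n_cols, size=2 * target + 8)
    if intra:
        r, c = np.minimum(r, c), np.maximum(r, c)
    flat = np.unique(r.astype(np.int64) * n_cols + c)
    if len(flat) > target:
        flat = rng.choice(flat, size=target, replace=False)
    r, c = flat // n_cols, flat % n_cols
    v = rng.integers(1, max_value + 1, size=len(r)).astype(np.float64)
    return ContactMatrix.from_coo(chrom_a, chrom_b, resolution, n_rows, n_cols,
                                  r, c, v)
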