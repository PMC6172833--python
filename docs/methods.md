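# Methods

## Coordinate model

All coordinates are 0-based half-open internally. Region strings
(`chrom:start-end`, thousands separators tolerated) are **also read as 0-based
half-open**, verbatim: `chr12:15,000,000-25,000,000` denotes exactly 10 Mb and
spans exactly 400 bins at 25-kb resolution. This is the convention of most
Hi-C tooling (e.g. cooler's region strings) and keeps `parse(render(iv)) ==
iv` trivially exact; it differs by one from the UCSC browser's 1-based
position box, which users pasting UCSC positions should note. Intervals
running past a chromosome end are clipped with a warning rather than
rejected, as a browser would. Chromosome names match exactly first, then with
the `chr` prefix added or removed. The chromosome table's order is canonical:
it fixes which chromosome supplies the rows of an inter-chromosomal matrix
(the earlier one), so keying is deterministic even when two chromosomes have
equal bin counts. SNP annotations resolve to 1-bp intervals; virtual-4C
windows are built by flank expansion (default ±1 Mb, the CLI `--flank`).

## Container byte layout

The layout (documented normatively in `butlr.py`; any change requires a
version bump) is little-endian with fixed-width fields so every index
position is computable: an 8-byte magic tag, uint16 version, length-prefixed
assembly and normalization labels, uint32 resolution, the chromosome table,
then a matrix directory (kind, chromosome indices, dims, uint64 offset of the
row index). Each matrix stores `n_rows + 1` uint64 absolute offsets followed
by row records: uint32 nonzero count, sorted uint32 column ids, float32
values. Empty rows occupy zero bytes. Values are quantized to float32 on
write; integer counts below 2^24 survive exactly. Intra matrices keep only
the upper triangle — symmetric input is folded, and (i,j)/(j,i) entries that
disagree by more than 1e-5 relative are a hard error rather than being
silently averaged, since such disagreement indicates an upstream bug. The
payload is deliberately uncompressed: seek offsets remain valid byte ranges,
so the file can be served by any range-capable HTTP server; whole-file gzip
is left to the user. One file holds one resolution; multi-resolution data is
a set of files.

A query reads the header, the slice of row offsets covering the rows it
needs, and those rows' records — nothing else. The `ButlrFile.bytes_read`
counter exposes this contract; on a 10,000-bin, 1%-dense matrix a query over
1% of rows reads on the order of 1% of the file (measured by
`scripts/acceptance.py`).

## Pairs binning

The pairs reader accepts whitespace/tab-delimited text with columns `readID
chrom1 pos1 chrom2 pos2 [strand1 strand2 [mapq1 mapq2]]` and `#` comments;
positions are 1-based 5′ coordinates as in the common pairs interchange
dialect. Uniquely-mapped filtering is approximated by `mapq >= 30` (default)
when mapq columns are present; files without them are assumed pre-filtered.
Inter-chromosomal pairs are dropped by default — the usual intra-only Hi-C
pipeline — and binned into rectangular matrices when requested. Every input
record is accounted for: retained + low-mapq + unknown-chromosome +
out-of-range + inter-dropped equals the total, and the rejects report can be
written as TSV.

## ICE balancing

Iterative correction assumes observed counts factor as `M_ij = b_i b_j T_ij`
with `T` having uniform marginals. Bins with zero marginal are masked before
iterating. Each sweep divides by the outer product of the normalised row
sums; convergence is `max_i |s_i/mean(s) − 1| < tol` (default 1e-5, at most
200 sweeps). Non-convergence is a flagged warning, not an error. The balanced
matrix is rescaled so its total equals the input total (keeping values on a
count-like scale) and biases are returned with unit geometric mean, the
convention of the standard ICE implementation; the multiplicative zero
pattern is preserved exactly. On noiseless planted-bias matrices recovery is
exact to numerical precision. Limitation: matrices whose support pattern is
not balanceable (e.g. structureless sparse matrices with pendant bins —
unlike real contact maps, which have full near-diagonal support) settle at a
nonzero row-sum deviation and are reported as non-converged.

## Virtual 4C

The signal at window bin `j` is the mean of `M[i, j]` over the bait's bins
`i`, so a single-bin bait with no smoothing is exactly the matrix row
restricted to the window — an identity tested against the container's region
query. Optional smoothing is a centred moving average over an odd number of
bins (default 1, i.e. raw), truncated at window edges rather than padded.
bedGraph output writes explicit zero bins so track extent is unambiguous.

## TAD calling

The directionality index uses a 2-Mb window by default (the published choice
of the original directionality-index pipeline; windows truncate at chromosome
ends) on ICE-normalised matrices. Segmentation replaces the original HMM —
whose parameters are not recoverable — with a deterministic heuristic:
median-smooth the DI (span 3 bins), set the threshold to one robust standard
deviation (1.4826 × MAD, falling back to the plain SD when the MAD is zero),
and place a boundary at the first bin above +threshold following an excursion
below −threshold with no opposite crossing in between. Domains are maximal
runs between boundaries, minimum 3 bins. On simulated maps with 10 planted
boundaries per 200-bin chromosome (enrichment τ = 3, 5 × 10⁶ pairs) this
recovers ≈ 97–99% of boundaries within ±1 bin; calls on real data are
"directionality-index-style", not byte-identical to any particular hosted
track.

## DHS linkage

Every proximal × distal pair on one chromosome with midpoint-to-midpoint
distance ≤ 500 kb (inclusive) is evaluated; pairs are kept when Pearson
r is **strictly** greater than 0.7. Midpoint distance is symmetric and
order-free, the natural reading where no anchor convention is stated. The
correlation is computed as `cov / sqrt(var_p · var_d)` with population
moments and a single square root, which keeps exactly-representable inputs
exact (the strictness of the 0.7 cut is tested on integer vectors whose r is
exactly 0.7 in IEEE arithmetic). Zero-variance profiles make r undefined;
such pairs are skipped with a warning. Signals are correlated raw by default
with an opt-in `log1p` transform. Retention is monotone in both thresholds.

## Synthetic data

`simulate_hic` draws independent Poisson counts on the upper triangle with
intensity `b_i b_j (1 + |i−j|)^(−α)`, multiplied by τ when both bins share a
planted domain, scaled so the expected total equals the requested depth
(spread over chromosomes by squared bin count). Defaults α = 1 (a typical
Hi-C decay regime) and τ = 3; Poisson is the simplest model consistent with
count data. `simulate_pairs` re-emits each simulated count as one read pair
uniform within its bins with random mate order — binning the file regenerates
the truth matrices exactly — plus a Binomial(depth, inter_fraction) dose of
uniform inter-chromosomal pairs. `simulate_translocation` adds to uniform
background a block decaying as `(1 + da + db)^(−α)` into the quadrant joined
by the fusion, where da, db are bin distances to the breakpoints —
reflecting that on the derivative chromosome those loci are `da + db` apart —
with the mirrored quadrant added when the rearrangement is reciprocal.
`simulate_dhs_table` gives each proximal site a latent cell-type profile;
linked distal sites mix the partner's latent with noise
(`√ρ·latent + √(1−ρ)·noise`, expected Pearson r = ρ) and sit within 500 kb;
unlinked sites are independent with uniform positions. All generators are
pure functions of (parameters, seed).

What the generators do **not** emulate: restriction-fragment structure,
mappability and GC bias beyond a smooth multiplicative factor, compartment
(A/B) plaid patterns, loop peaks, nested or hierarchical domains, and
heavy-tailed count dispersion. Passing tests therefore demonstrate that the
algorithms meet their contracts under the stated generative model, not that
boundary recovery or linkage precision will match these numbers on real
tissue data.

## Problem sizes and numerical choices

The test suite and acceptance script use matrices up to 10,000 bins, 50
round-trip fixtures up to 2,000 bins, 200 randomized queries, 10 TAD
simulation replicates of 200 bins at 100 kb with 5 × 10⁶ pairs, and DHS
panels of 40 × 200 sites over 120 cell types — sizes at which every check
is exact or tightly concentrated while the whole suite stays fast. Ties and
degenerate inputs: all-zero matrices encode to flat row indexes and query to
zeros; all-masked matrices are a degenerate-input error for ICE; DI is set to
0 where its window sums are zero or equal; boundary placement is
deterministic, so repeated calls agree bit-for-bit.
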