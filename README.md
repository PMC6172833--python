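# butlrkit

An indexed binary storage and analysis backend for Hi-C contact matrices —
the data layer behind a query-driven 3D-genome browser, usable as a Python
library or from the shell.

Hi-C experiments produce genome-wide contact matrices that, stored as dense
tab-delimited text at high resolution, run to hundreds of gigabytes and force
any viewer to scan whole files to draw one region. butlrkit addresses this
with a **BUTLR-style container** (Binary Upper Triangular MatRix): only the
nonzero values of the upper triangle of each intra-chromosomal matrix (and
the full rectangle of each inter-chromosomal matrix) are stored, binarized,
behind a two-level index — a header directory locating every matrix, and a
per-matrix row index delimiting every row's record. A region query then seeks
straight to the rows it intersects instead of reading the payload, which is
exactly the access pattern needed to serve files over plain HTTP range
requests. Around the container, the package implements the standard
computations of a Hi-C backend:

- **Pairs binning** — read pairs with positions (chrom1, pos1, chrom2, pos2)
  are assigned to fixed-width bins (`n_c = ceil(length / resolution)` bins per
  chromosome); each retained pair increments one matrix cell. Inter-chromosomal
  pairs are dropped by default, or binned into rectangular matrices on request.
- **ICE balancing** — iterative correction removes multiplicative per-bin
  biases: repeat `b_i ← s_i / mean(s)`, `M_ij ← M_ij / (b_i b_j)` until row
  sums `s_i` are uniform, returning the balanced matrix and the bias vector.
- **Virtual 4C** — a one-vs-many profile: the mean contact of a bait locus's
  bins with every bin of a window, written as bedGraph.
- **TAD calling** — the directionality index
  `DI_i = sign(B−A) · ((A−E)²/E + (B−E)²/E)` with `A`/`B` the up/downstream
  contact sums within a window and `E = (A+B)/2`; domain boundaries are
  placed where the smoothed DI crosses from strongly negative to strongly
  positive.
- **DHS linkage** — proximal and distal DNase-hypersensitive sites are paired
  when their accessibility profiles across a cell-type panel have Pearson
  r > 0.7 and the sites lie within 500 kb of each other.
- **Synthetic data** — seeded generators for all of the above with recorded
  ground truth: TAD-structured matrices with power-law distance decay, pairs
  files, inter-chromosomal translocation signatures (reciprocal or not), and
  DHS panels with planted linkages.

## Worked example

Simulate a two-chromosome genome, bin the pairs, build the indexed file, and
query it:

```sh
printf 'chr1\t20000000\nchr2\t16000000\n' > genome.sizes
butlrkit -q simulate pairs --chrom-sizes genome.sizes --resolution 100000 \
    --depth 500000 --boundaries 5 --inter-fraction 0.05 --seed 7 -o demo.pairs
butlrkit -q convert --pairs demo.pairs --chrom-sizes genome.sizes \
    --resolution 100000 --keep-inter -o demo.butlr
butlrkit -q info demo.butlr
```

```
format version: 1
assembly: custom
normalization: raw
resolution: 100000
chromosomes: 2
  chr1  20000000
  chr2  16000000
matrices: 3
  chr1  intra  200x200  @118
  chr2  intra  160x160  @138590
  chr1 x chr2  inter  200x160  @228038
```

The directory lists two intra matrices and one inter matrix (the 5% of
simulated pairs that joined chr1 and chr2), each with the byte offset of its
row index. A region query returns a dense, symmetric block of binned counts —
here 5 × 5 bins of 100 kb:

```sh
butlrkit -q query demo.butlr --region chr1:2,000,000-2,500,000
```

```
365  169  114  100  79
169  383  169  127  109
114  169  321  174  118
100  127  174  342  206
79   109  118  206  371
```

Counts are largest on the diagonal and decay with distance, as contact
frequencies do. A virtual-4C profile around a bait bin shows the same decay
centred on the bait (368 at the bait's own bin, falling off both ways):

```sh
butlrkit -q v4c demo.butlr --bait chr1:3,000,000-3,100,000 --flank 300000 -o bait.bedgraph
```

```
chr1  2700000  2800000  97
chr1  2800000  2900000  112
chr1  2900000  3000000  185
chr1  3000000  3100000  368
chr1  3100000  3200000  161
chr1  3200000  3300000  116
chr1  3300000  3400000  82
```

The remaining subcommands follow the same pattern: `ice` balances a matrix
text file, `tads` writes called domains as BED (alternating-color BED9 with
`--bed9`), `linkage` filters a DHS site table, and `validate` checks a
container's structural integrity. The same operations are available in
Python (`butlrkit.encode_butlr`, `ButlrFile.query`, `ice_normalize`,
`virtual_4c`, `directionality_index`, `call_tads`, `dhs_linkage`, ...).

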