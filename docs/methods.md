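# Methods

This note records the models, conventions, defaults and numerical choices
behind `hicpile`, and what the simulation-based tests do and do not show.

## Coordinates, bins and the cooler dialect

All genomic coordinates are 0-based half-open base pairs. A bin grid of
size `binsize` tiles each chromosome from its start; the last bin may be
short; bin id = floor(position / binsize) plus a per-chromosome offset, in
the declared chromosome order (which is authoritative for all sorting).

Contact files are read and written in the cooler HDF5 dialect: `chroms`,
`bins`, `pixels` (sparse COO triples with `bin1_id <= bin2_id` and positive
raw counts, sorted by bin1 then bin2) and `indexes` (`chrom_offset`,
`bin1_offset`); multi-resolution files nest one such group per
`resolutions/<N>`. Only the upper triangle is stored; `fetch` mirrors
triples across the diagonal so queries are unconstrained, and
`fetch(r1, r2)` equals `fetch(r2, r1)ᵀ` (raw exactly; balanced up to
float multiply-order rounding, ~1e-15 relative).

Balanced counts use the cooler multiplicative convention
`balanced = raw · w_i · w_j` with per-bin weights read from the file
(column name configurable, default `weight`). A NaN weight marks a bin
filtered out by balancing: every balanced value in its row/column is
missing — including cells with no stored pixel, since a balanced zero at a
filtered bin is undefined, not zero. Raw queries are never affected.
Balancing weights are always read or simulated, never estimated; ICE/KR
style balancing is out of scope.

## Pair coordinate arithmetic

`snap_to_bins` maps each anchor to the single bin containing its
representative point: anchor start, midpoint (floor of (start+end)/2), or
last base. The default is the midpoint, the least biased single-bin
representative given that loop callers emit variable anchor widths; exact
midpoint ties resolve by floor. Intra-chromosomal pairs are reoriented so
bin1 ≤ bin2. The operation is idempotent.

`expand_pixels` grows single-bin anchors to (2·buffer+1)-bin square
footprints. Footprints that would leave the chromosome are **flagged**,
never clipped — clipping would silently produce unequal submatrix shapes
on the regular path; callers drop flagged pairs with a logged count.

`remove_short_pairs` measures a footprint's clearance from the diagonal in
bins (the diagonal is a bin-grid object): a pair survives iff
`min_col_bin − max_row_bin ≥ padding_bins`, equivalently iff no footprint
cell (i, j) has j − i < padding. A base-pair padding is converted with
ceiling division. Inter-chromosomal pairs always survive.

## Block-processed extraction

Queries are grouped into square genome tiles (default side 10 Mb — a
~1000×1000 dense rectangle at 10 kb bins, comfortably in memory while
amortizing per-fetch overhead). A footprint straddling a tile edge stays
with the tile of its top-left corner, and that tile's fetch extent is
enlarged just enough to contain it, so each query is served by exactly one
dense fetch and peak memory is bounded by one (enlarged) block per file in
flight, independent of query count. Because every scatter is independent,
results are bit-identical across block sizes and query orders; the test
suite asserts this, and instruments the fetch path to verify the memory
bound. A footprint larger than the block span is an error instructing the
caller to raise `block_span_bp`.

Results persist to a single HDF5 container (layout_version attribute,
checked on load): a counts dataset chunked along the interaction axis (so
one interaction is one chunk read), plus offsets/dims tables for jagged
stacks and a serialized interaction table. Loading keeps counts as a lazy
h5py dataset; slicing commutes with the round trip. Delayed-operation
composition over stored arrays is not provided — only random-access
slicing.

## Loop merging

Calls pooled from all input lists are snapped to a common grid and
clustered per chromosome-pair namespace with DBSCAN, `min_samples=2`,
Manhattan distance on (bin1, bin2) scaled by the bin size, `eps = radius`
in base pairs. With minPts = 2 any point within eps of another is itself
core, so the clusters are exactly the connected components of the
≤eps-distance graph (asserted against an independent transitive-closure
oracle); DBSCAN "noise" — isolated calls — become singleton clusters
rather than being discarded, because dropping unreplicated calls is a
filtering decision, not a merging one. `radius = 0` merges exact
duplicates only. Manhattan on snapped bins makes the radius interpretable
in base pairs and robust to sub-bin jitter.

Representative selection: `max_metric` (argmax of a metadata column, ties
to the first call in concatenation order), `most_frequent` (modal pixel,
ties broken by the metric when present, else first), or `mean_position`
(member nearest the coordinate-wise mean). The default is `max_metric`
when a metric column is supplied, else `most_frequent`. The merged object
keeps the full concatenated input, source labels, per-call cluster ids,
cluster membership lists and the winning selection value per cluster.

## Loop-strength enrichment

Score = (median(foreground) + 1) / (median(background) + 1) over the
(2·buffer+1)² window; the +1 pseudocount keeps sparse windows finite and
is recorded in `score_definition`. Defaults: buffer 5 (11×11 window),
foreground = focal pixel, background = donut at Chebyshev radius 2–5 with
the center row and column excluded to avoid stripe contamination (an
option re-includes them). Raw counts are the default input (medians of
integers); balanced input is supported with missing cells excluded from
both medians, and an all-missing background yields a missing score rather
than an error. Windows overlapping the diagonal band are scored with a
warning; filtering with `remove_short_pairs(padding ≥ buffer)` avoids it.
No significance testing and no expected-matrix normalization are
performed.

## Aggregation and pileups

Reductions are missing-aware with a per-cell contributor count
(`n_contributing`); a cell with zero contributors is NaN. APA uses the
mean (not the sum) so values are comparable across pair-list sizes, and
per-file outputs are kept separate.

`regularize` resamples an r×c matrix to ndim×ndim by bilinear
interpolation on the unit square: cell centers map to (i+0.5)/n, and
target coordinates beyond the source center range are **clamped** (not
extrapolated), which makes resampling at native size an exact identity.
Matrices with a side < 2 cannot be interpolated and are dropped with a
logged count. `scale_to_sum` rescales the output to the source total
(guarded against zero-sum sources).

`pileup_domains` widens each domain [s, e) by `buffer_frac`·(e−s) on each
side (default 0.5), snaps outward to whole bins, extracts the square
on-diagonal block (a jagged stack), by default divides each block by its
total so every domain contributes equal weight regardless of depth, then
regularizes to `ndim` (default 100) and averages. `pileup_boundaries`
takes the boundary's bin plus `flank_bp // binsize` bins each side — an
odd window with the boundary bin at the exact center. Boundary output is
interpreted as a boundary-centered pileup; compartment-strength saddle
binning and observed-over-expected normalization are out of scope.

## The simulator

Noiseless intensity per chromosome:

    Λ_ij = depth · (|i−j|+1)^(−α) · L_ij · T_ij · b_i · b_j

with α the distance-decay exponent (default 1, the classic fractal-globule
regime), L a product of loop bumps `1 + (fold−1)·exp(−d²/(2·width²))` in
Chebyshev distance d from the loop pixel (mirror-symmetrized), T
multiplying `fold` inside each TAD block, and b a positive per-bin bias
(`make_bias` draws log-normal with unit mean). Counts are
Poisson(Λ) on the upper triangle, mirrored; stored weights are exactly
1/b, so balanced counts have bias-free expectation — which is what the
balancing-recovery test measures per distance band. All randomness flows
from a single seed; identical (spec, seed) produce byte-identical files
(HDF5 timestamps are disabled).

Poisson noise was chosen over negative binomial for closed-form
expectations and standard errors; biological overdispersion,
inter-chromosomal contacts, and compartment checkerboards are not
emulated. Passing tests therefore demonstrate algorithmic correctness and
calibration under a clean generative model, not robustness to the full
noise structure of real Hi-C libraries.

`simulate_loop_calls` emulates replicate loop-caller output: each true
loop appears with probability 1−fnr, displaced by an offset drawn
uniformly from the **Manhattan ball** of radius `jitter_bins`. Bounding
jitter in the same metric the merger clusters with gives a hard guarantee:
two calls of one loop are at most 2·jitter apart, so a merge radius of
2·jitter bins always reunites them, while loops ≥ 6 bins apart can never
cross-link. (With offsets drawn from the full square, two calls can be
Manhattan distance 4·jitter apart and the guarantee fails ~21% of the time
per loop at jitter 1 — enumerable over all 9³ offset triples — so the
ball is the self-consistent choice.)

## Problem sizes and test design

The simulation used throughout the tests and the acceptance script is a
two-chromosome genome (5 Mb + 3 Mb) at 10 kb bins (800 bins, ~57 planted
fold-5 loops 12 bins apart at a fixed 40-bin distance, fold-3 TADs, bias
sd 0.3 on the log scale, depth 1000) — large enough that every contract is
exercised across chromosome boundaries and the enrichment medians are
Poisson-stable, small enough that the whole suite runs in seconds.
Extraction correctness is asserted against brute-force lookups in the
simulator's dense matrices (integer-exact raw, ≤1e-9 relative balanced);
merging against a hand-coded transitive-closure oracle; regularization
against an independently coded 4-neighbour bilinear loop (≤1e-12).

## Known limitations

- Only the cooler dialect is supported; the `.hic` binary format is not
  parsed (one open format suffices to exercise every method).
- Balancing weights are consumed, never estimated.
- The jagged path stores one flat buffer per result; very large jagged
  stacks trade random-access granularity for simplicity.
- DBSCAN merging is exact for minPts = 2; other minPts values would break
  the connected-components equivalence the contracts rely on and are not
  exposed.
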