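# Methods

## Graph model

A 4D functional volume (X×Y×Z×T) and a binary mask define an undirected
weighted graph: nodes are the N in-mask voxels, edges the N(N−1)/2
unordered voxel pairs, weights their Pearson or Spearman correlations.
voxgraph computes two node statistics on this graph — degree centrality
(DC, global connectivity) and local functional connectivity density
(lFCD, connectivity restricted to the spatially contiguous neighbourhood)
— each in a binary (edge count) and a weighted (summed correlation)
variant.

Voxels are ordered by a C raster scan of the mask (x slowest, z fastest),
0-based; this ordering is pinned by tests because every per-voxel output
and every streamed pair enumeration inherits it. Any nonzero mask value
is in-mask. In-mask voxels with constant time series have no defined
correlation; they are removed at load time with a warning and appear as 0
in all output maps.

## Correlation engine

Rows are centered and scaled to unit L2 norm, so Pearson r is a dot
product; Spearman applies a within-row average-tie rank transform
(`scipy.stats.rankdata`) first. The upper triangle is streamed in i-major
order as matmul strips of `block_size` rows against all later rows
(float64 accumulation): peak additional memory is O(block_size·N), never
O(N²), and results are independent of `block_size` (integer outputs
exactly, float outputs to ~1e-15 from re-associated sums). Default
`block_size` 1024 keeps a whole-brain strip in tens of MB. Computed r
values are clipped to [−1, 1] to absorb rounding at perfect correlations.

## Thresholding

**Correlation threshold.** Strict inequality: a pair counts iff
`r > r_threshold` (default 0.0). Consequently pairs at exactly r = −1
require a threshold strictly below −1, which the config permits.

**Sparsity.** A target of P % keeps `k = ceil(P/100 · N(N−1)/2)` edges —
the at-least-P% reading; the algorithm may overshoot (ties), never
undershoot. The selection uses the two-level adaptive histogram:

- Primary histogram: 50 equal bins spanning `[floor_threshold, 1.0]`
  (floor default 0.0; lowering it widens the bins — the span is divided,
  not extended). Records are stored per bin as chunks of (i, j, r)
  arrays. A record is admitted iff `r` strictly exceeds the admission
  threshold, which starts at the floor.
- Pruning: after each insertion batch, while the bins strictly above the
  lowest retained bin hold ≥ k records, the lowest bin is discarded and
  the admission threshold rises by exactly one bin width. Pruning repeats
  until the condition fails, so after a burst of strong edges the
  admission threshold can climb several bins at once, up to the bin just
  below the survivors. Discarded records can never belong to the top-k
  (there are provably ≥ k records strictly above their bin), and every
  record in never-discarded bins was admissible whenever it arrived, so
  the final selection is independent of streaming order — both properties
  are oracle-tested.
- Finalization: whole primary bins are taken high→low while they fit
  under k; the boundary bin is re-histogrammed into 100 equal sub-bins
  over its own range and taken high→low until the cumulative count
  reaches k, the last sub-bin in full. `final_threshold` is the weakest
  retained r. Values separated by more than one sub-bin width —
  `span/(50·100)`, i.e. 2×10⁻⁴ of the span at default settings — can
  never be conflated at the boundary; the overshoot is exactly the
  boundary sub-bin's tie group.
- Shortfall: if fewer than k correlations exceed the floor, everything
  stored is used and a warning is raised.

Weighted DC sums the raw retained r values (no rescaling). Accumulation
sorts retained records by (i, j) before scattering, so weighted maps are
reproducible to well under 1e-10 regardless of arrival order. The
degree-sum identity `Σ_i DC_b(i) = 2·retained` holds by construction and
is asserted on every result object.

An exact-sort reference (`dc_sparsity_exact`, O(N²) memory) exists for
validation; it breaks exact ties arbitrarily where the histogram keeps
whole tie groups, which is the one place the two may differ.

## lFCD region growing

For each target voxel, breadth-first search over the 26-neighbourhood
(face-, edge-, corner-touching in index space; voxel anisotropy is
ignored) admits a voxel iff its correlation **with the target** — not
with the neighbour it was reached through — strictly exceeds the
threshold. Growth stops at the mask boundary. The seed is a member with
weight 1.0 by default (`include_seed=False` toggles the
neighbours-only reading). Correlation rows are computed per strip of
targets, so memory stays O(block_size·N). The grown cluster equals the
26-connected component of the thresholded indicator volume containing the
target; tests check this against `scipy.ndimage.label` for every voxel of
random fixtures, along with monotone shrinkage in the threshold,
idempotence, and the bound `lFCD_b ≤ DC_b + 1` at equal threshold.

## Concordance

Lin's concordance correlation coefficient with population (1/n) moments:
`ρ_c = 2·cov(a,b)/(var(a)+var(b)+(ā−b̄)²)`. Computed over in-mask voxels
only. Identical maps (including constant ones) score exactly 1.0 by an
explicit short-circuit; two unequal constant maps are undefined and
return NaN with a warning; one constant map against a varying one scores
0. The statistic is symmetric, bounded by |Pearson r|, invariant under a
shared affine remap, and strictly below 1 under any pure scale or shift —
which is what makes it the right cross-implementation agreement score.

## Synthetic fixtures

Voxel v in a block with latent g_k gets
`x_v = w·g_k + (1−w)·ε_v`, with g_k, ε_v independent Gaussians (latents
unit variance, noise scaled by `noise_sd`); unassigned in-mask voxels
(the shell) carry pure noise. Expected within-block correlation is
`w²/(w² + (1−w)²·noise_sd²)`, cross-block 0; the empirical mean is tested
to converge to the formula within ±0.02 at T = 2000. Draw order is fixed,
so a seed pins the volume bit-for-bit.

Two stock layouts set the validation conditions:

- `two_block_spec` — two 3³ cubes, 2 empty planes apart, T = 100. With
  `signal_weight=1, noise_sd=0` it is the noiseless limit: within-block
  r ≡ 1, so binary DC at threshold 0.6 is exactly blocksize−1 and binary
  lFCD exactly blocksize for every block voxel (cross-block |r| stays
  below 4/√T for independent latents).
- `demo_spec` — 10³ grid, two coherent 5³ blocks (w = 0.8, noise sd 1,
  expected within-block r ≈ 0.94), 350 pure-noise shell voxels, 600
  in-mask voxels, T = 50.

The generator emulates block-structured correlation only; real fMRI has
temporal autocorrelation, physiological drift, spatial smoothness and
motion structure, none of which are modelled. Passing tests therefore
demonstrate algorithmic correctness (selection, growing, accumulation,
memory bounds), not robustness to realistic noise, and say nothing about
preprocessing choices upstream.

## Validation sizes and numerical choices

Oracle sweeps use ≥100 random instances at N ≤ 200, T = 50 for sparsity
mode, N ≤ 100 for the exhaustive threshold oracle, 6³ grids for per-voxel
lFCD checks, and N = 5000 for the memory contract (traced peak ~23 MB vs
the 200 MB full matrix, checked under a quarter of it) — sizes chosen so
the whole suite validates every contract in a few seconds while keeping
the pair counts (up to ~12.5 M streamed correlations) large enough to
exercise pruning. Degenerate inputs fail fast with typed errors: masks
selecting < 1 voxel, T < 3, zero-variance rows reaching the correlation
engine, empty histograms, out-of-range configs.

## Known limitations

- Sparsity overshoot is unbounded in the worst case (a massive tie group
  in the boundary sub-bin is kept whole); the tie precision only bounds
  the *value range* of the extras, not their count.
- lFCD is O(N·cluster) per target with a Python BFS; whole-brain masks at
  full resolution will be slow compared to the vectorized DC paths.
- No auto-masking and no preprocessing (detrending, band-pass, motion):
  inputs are assumed analysis-ready, and the mask is always explicit.
- Spearman mode ranks once per run; tied samples get average ranks.
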