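# Methods

This note documents the models and procedures `clupaq` implements, the
parameters that matter, the numerical conventions, and what the synthetic
test bed does and does not establish.

## Coordinate conventions

All computation is done on 0-based integer column indices of the rectangular
spectra-by-frequencies matrix; a ppm axis, when supplied, is carried as
presentation metadata only. All index intervals are half-open `[start, end)`.
Mixing index and ppm arithmetic is a classic source of off-by-one drift, so
exactly one frame is authoritative.

## Peak detection

The detector computes a continuous wavelet transform (Mexican-hat mother
wavelet, via PyWavelets) over a geometric scale ladder
(1, 2, 3, 4, 6, 8, 12, 16, 24, 32, 48, 64 points by default — the ladder
should reach about the half-width of the broadest expected line). Local
coefficient maxima are linked across scales, largest scale first, into ridge
lines; a ridge may skip `gap_thresh` (2) scales before closing, and a match
window of max(3, scale) points absorbs the apex drift that widening scales
induce. A ridge is accepted when it persists over at least a quarter of the
ladder and its strongest coefficient exceeds `min_snr` (3) times the local
noise floor, estimated as the 95th percentile of absolute smallest-scale
coefficients within ±200 points. The reported position is the ridge's point
at the smallest scale reached (best localisation); the reported intensity is
the raw spectrum value there, because the noise floor users reason about —
`baseline_thresh`, e.g. 50 000 on typical instrument scales — is in raw
intensity units.

Whole-spectrum CWT is slow and insensitive to weak lines next to dominant
ones, so detection runs on a four-segment window sliding one segment
(`segment_size`, default 1024, a power of two) at a time; the 3-segment
overlap protects peaks in segment margins. Duplicate detections from
overlapping windows within 2 indices collapse to the more intense one.
`baseline_thresh` defaults to 0 and must be chosen per dataset — the right
floor depends on instrument scaling and is deliberately not guessed.

## Reference selection

For peak lists S (candidate) and T, the directed distance is
`d(S, T) = Σ_{p_T∈T} min_{p_S∈S} |p_S − p_T|` (asymmetric: every peak of T is
charged to its nearest neighbour in S). The reference maximises
`goodness(S) = −Σ_{T≠S} d(S, T)`; ties take the lowest row index. Nearest
neighbours are found by binary search on the sorted candidate list, keeping
the cost well under the quadratic bound. Two documented properties are
deliberately preserved rather than "fixed": a candidate with many spurious
peaks is favoured (extra peaks can only shrink nearest-neighbour distances),
and outlier spectra with few, low peaks rank at the bottom of the goodness
table — which doubles as an outlier diagnostic.

## CluPA alignment

Per target, aligned against the fixed reference row:

1. **Region.** The working region is bounded by the lowest target-intensity
   point between the segment start and the leftmost merged peak, and
   likewise on the right (earliest index on ties). Quiet boundary points
   make rigid shifts cheap at the seams.
2. **Lag.** The best integer lag maximises the circular FFT
   cross-correlation of the reference and target regions after each is
   raised to its own minimum, restricted to `|lag| ≤ max_shift`. Ties
   resolve to the smallest |lag|, then the negative one. **Sign
   convention:** the lag is the displacement *added* to target indices — a
   target delayed by k points yields −k.
3. **Shift.** Intensities and target-owned peak positions inside the region
   translate rigidly; vacated points take the nearest surviving edge value
   (constant extension invents no signal, and keeps totals exact when the
   flanks are zero). Peaks that would leave the region are clamped to its
   edge, counted in the trace, and kept (dropping them could orphan a
   subtree).
4. **Recurse.** The dendrogram is built on the *post-shift* merged peak
   positions (scipy agglomerative linkage — average by default, single and
   complete available) and cut below the root into two clusters; the
   spectral boundary is the midpoint between the left cluster's maximum and
   the right cluster's minimum. A child recurses only if it holds peaks of
   both spectra and at least `min_peaks_to_recurse` (3) entries. Shifting
   before clustering is the load-bearing ordering: it removes most of the
   displacement before peak grouping, so the two-way cut rarely splits
   corresponding peaks.

The recursion is implemented with an explicit work stack; every child holds
strictly fewer peaks than its parent, so termination is structural.
`max_depth` (default unbounded) caps the recursion — depth 0 degenerates to
a single rigid shift, which is useful as a baseline and in diagnostics.
`max_shift` defaults to 100 points (≈ 0.05 ppm at common digital
resolutions). An `exclude_mask` of intervals freezes any region overlapping
it (lag 0).

Alignment quality is evaluated as the mean pairwise Pearson correlation
between spectra, and — on synthetic data with known truth — as residual
peak misalignment, measured per peak as the displacement maximising a local
cross-correlation of the line shape around the reference apex. A single
argmax is *not* used for this: additive noise jitters the apex of a
realistic line by ±1–2 points, which would be charged to the aligner.

## BW-ratio quantitation

With groups k of sizes n_k, grand column mean x̄_.j and group means x̄_kj,

    BW(j) = Σ_k n_k (x̄_kj − x̄_.j)² / Σ_k Σ_{i∈k} (x_ij − x̄_kj)² .

The size-weighted numerator makes the identity BW = F·(K−1)/(N−K) with the
one-way ANOVA F exact, which the tests assert against an independent F
computation. Degenerate columns: 0/0 (no variance at all) is defined as 0
and flagged; a positive numerator over a zero denominator is an +inf
sentinel, flagged, and counted as significant only against the
finite-sample critical value.

**Bootstrap null.** Each column is centred by its group means (all group
means become exactly 0); per iteration, each column independently redraws N
values with replacement from its centred pool and the original group sizes
are reassigned. One seeded generator drives the whole bootstrap and the
seed is echoed in the report. Columns are resampled independently — the
plainest reading of per-frequency resampling; sharing resampling indices
across columns (preserving spectrum-level structure) is a known alternative
this package does not implement, consistent with not modelling
inter-frequency correlation at all.

**Critical values.** Per-frequency empirical quantiles at `1 − alpha/n_peaks`
by default (`method="higher"`, conservative); `pooled=True` pools all null
samples into one scalar threshold. `n_peaks` is the Bonferroni-style divisor:
columns of one NMR line are redundant, so the adjustment counts *peaks* (the
pipeline uses the average detected peak count per spectrum, rounded;
overridable), not columns. When the adjusted tail is finer than the
bootstrap resolution (level < 1/B per column), the maximum sample is
returned with a warning — at that point the per-column false-positive rate
is ~1/(B+1), so for strongly adjusted analyses the pooled threshold, whose
resolution is B × n_columns, is the better tool. Significant regions are
maximal runs of consecutive super-critical columns.

A consequence worth knowing: for a peak that differs between groups in
*position* rather than height, the BW maximum sits on the peak's shoulders
(steepest slope, largest mean difference), not at its apex — a constructed
case in the tests demonstrates this.

## Synthetic cohorts

The generator sums Lorentzian lines `h·w²/((x−a)² + w²)` — the natural NMR
line shape — plus i.i.d. Gaussian noise, and applies integer shifts
(global, or independently per disjoint region), so ground truth is exact for
CluPA's rigid integer shifts. Group effects add a constant
`effect_size · noise_sd` to designated columns of one group. Everything is
deterministic given the seed, and cohorts round-trip through the text I/O
losslessly.

Default study conditions used by the test suite and the acceptance script:
10 spectra × 8192 points with 15 peaks (heights 60–150, widths 4–10,
noise sd 5 → peak SNR ≈ 20) and global shifts uniform on [−50, 50] for
shift recovery; a 6-peak/two-cluster cohort with opposite per-region shifts
(k ≤ 40) for the recursion test; 2 × 10 spectra × 2000 pure-noise columns
with 500 bootstrap draws for type-I calibration (a desk-scale budget chosen
as ~half the draws a full analysis would use); and 50 replicates of a
3-within-SD effect at n = 10 per group for power. What these simulations do
**not** emulate: correlated (pink/baseline) noise, intensity-dependent noise,
peak-shape changes between samples, covariation of peaks from one molecule,
and non-integer or locally elastic shifts. Passing tests therefore show the
algorithms do what they claim under clean line shapes and rigid shifts —
they do not certify performance on instrument data with baseline roll or
heavy peak overlap.

## Known limitations

- Rigid integer shifts per segment: genuinely elastic (warping) distortion
  within a segment is approximated, not modelled.
- The goodness criterion can elect an over-detected spectrum as reference;
  inspect the goodness table when detection parameters are uncertain.
- Inter-frequency correlation is ignored throughout; the per-column
  bootstrap is exchangeable within columns only.
- Bonferroni-style adjustment by peak count is conservative; no FDR
  alternative is provided.
- No raw vendor-format ingestion, binning, phasing or baseline correction:
  input is a processed numeric matrix.
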