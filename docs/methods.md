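# Methods

This note records the estimators, conventions and numerical choices the
package implements, the parameters that matter, and what the synthetic
validation does and does not establish.

## Phase-space entropies

All estimators embed the signal with delay 1 into overlapping templates
`X_i^m = (x_i, ..., x_{i+m-1})`, `i = 1..N-m+1` (0-based internally,
half-open windows `[i, i+m)`; 1-based in user-facing text). Tolerance
comparisons are inclusive (`d <= r`).

**ApEn** uses per-template probabilities `C_i^m = B_i^m / (N-m+1)` with
self-matching included, `Φ^m` the mean of `ln C_i^m`, and
`ApEn = Φ^m − Φ^{m+1}`. Self-matching keeps every probability positive,
so ApEn is defined for every finite input. The classical `N → ∞` form
is computed as the finite-N plug-in estimator, as in every practical
implementation.

**SampEn** counts matches with `i, j` both ranging over the first
`N−m` templates, `j ≠ i`, at dimensions `m` and `m+1`, and returns
`−ln(A/B)` on the aggregated counts. It is undefined when either
aggregate is zero. Because Chebyshev distances are non-decreasing in
the window length, `A <= B` and defined values are non-negative.

**RangeEnA / RangeEnB** substitute the normalised range distance

    d_range = (max|diff| − min|diff|) / (max|diff| + min|diff|)

for the Chebyshev distance in ApEn and SampEn respectively. The
distance lies in `[0, 1]` when defined, is symmetric, exactly invariant
to common offsets and joint non-zero rescaling, non-decreasing in the
embedding dimension (max|diff| grows, min|diff| shrinks), and undefined
exactly for element-wise identical templates.

Conventions adopted where the definition leaves room:

* **Self-pairs under the range distance** are undefined and therefore
  never match. In RangeEnA the per-template probability is normalised
  by the *candidate* count (template count minus one):
  `C_i^m = B_i^m / (N−m)`. This keeps the terminal property exact —
  at `r >= 1` every candidate matches, every `C_i = 1`, and
  `RangeEnA = 0` identically (likewise RangeEnB via `A/B = 1`) — while
  still allowing RangeEnA to be *undefined* whenever some template has
  no neighbour at all, which at small `r` makes it the most
  undefined-prone of the four measures. The alternative (forcing the
  self-pair to count as a match) would make RangeEnA always defined
  and is rejected for that reason.
* **Duplicate non-self templates** (zero denominator, `i ≠ j`) are
  counted as non-matches and tallied in `n_excluded_pairs`. For
  continuous-valued signals such ties have probability zero.
* **Undefined results** are a tagged state (`value=None`), serialised
  as blank CSV cells, and never averaged into summaries; undefined
  counts are reported alongside every summary table.
* **SD correction** (ApEn/SampEn only) divides the signal by its
  *population* standard deviation, which is algebraically the same as
  using tolerance `r·SD`. The range measures are amplitude-invariant
  by construction and never apply it, even if requested.

Defaults `m = 2`, `r = 0.2` follow the common usage range for these
measures; the tolerance grid is 0.01..1.00 in steps of 0.01 and the
dimension grid 2..10 at `r = 0.2`.

### Profiles and exponents

`entropy_profile` computes the pairwise distance matrices once per
(signal, m) and thresholds them across the whole tolerance grid; this
is arithmetically identical to independent per-point evaluation (the
counts are integers cut from the same matrix) and is tested to be
exactly equal. `fit_exponent` fits an OLS line of entropy against the
natural log of the grid (slopes under log10 differ only by a constant
factor). Following the sweep protocol, a profile with *any* undefined
point is not fitted (`skipped=True`); `n_points` is reported so users
can filter m-exponent fits, which rest on only 9 grid points.

Empirically (and tested at reduced scale), the RangeEnB r-exponent is
negative and flattens monotonically towards 0 as the generative Hurst
exponent grows; its rank correlation with H across an fBm sweep
exceeds 0.8 in magnitude, while uncorrected SampEn profiles on raw fBm
paths are mostly undefined somewhere on the grid and yield few usable
fits.

## Rescaled-range analysis

The curve builder splits the signal into `n = 1, 2, 4, ...` equisized
segments while the segment length `floor(N/n)` exceeds four samples,
discarding the tail remainder. Each segment is mean-centred, summed
cumulatively, and contributes `R/S` (range of the cumulative sum over
the population SD of the segment). Zero-SD segments are skipped rather
than fatal, to survive locally constant stretches of real recordings;
a scale with no surviving segments is dropped, and fewer than two
surviving scales is an error. The Hurst estimate is the OLS slope of
`ln(mean R/S)` against `ln(segment length)` — the classical R/S law;
regressing on the segment *count* instead would flip the sign and is
not what the power law describes. The estimate is not clipped.

**Input-kind convention.** R/S takes an increment-like series (the
procedure itself builds the walk). Applied directly to a motion-like
path the slope saturates near 1 irrespective of the true exponent
(measured: ≈0.99 for Brownian paths of N = 1000). `hurst_rs` therefore
takes `kind="noise"` (default: analyse as given — correct for white/
pink/brown noise, EEG-like recordings) or `kind="motion"` (difference
first — correct for fBm/fLm/Brownian paths). With N = 1000 the
estimator carries the well-known small-sample positive bias (white
noise ≈ 0.55, fBm H = 0.8 recovered at ≈ 0.79); no Anis–Lloyd
correction is applied, and recovery across H = 0.2/0.5/0.8 is strictly
monotone.

## Simulators

* **Noise.** White: iid `N(0,1)`. Pink/brown: the one-sided spectrum of
  white noise scaled by `f^(−β/2)` (β = 1, 2), zero-frequency bin set
  to 0, inverse-transformed and standardised to zero mean, unit
  variance. Chosen over AR approximations for an exact expected
  spectral slope.
* **fBm.** Exact Gaussian draw via Cholesky factorisation of
  `D·(t^{2H} + s^{2H} − |t−s|^{2H})/2` on integer times `t = 1..N`
  (grid units only rescale amplitude, which the range measures ignore
  and SD correction absorbs). Length is capped at 4096 (O(N³)
  factorisation); the factor is cached per (H, N), so sweeps at many
  seeds reuse it. The covariance scale `D` multiplies paths by `√D`
  exactly, which is what makes matched-seed covariance-scaling
  comparisons bitwise clean. Validated: empirical covariance at N = 32
  matches the model entrywise within Monte-Carlo error; H = 0.5
  increments are uncorrelated.
* **fLm.** Symmetric α-stable innovations from the
  Chambers–Mallows–Stuck transform (α = 2 reduces to Gaussian, α = 1
  to Cauchy), FFT-convolved with the truncated moving-average kernel
  `a(k) = (k+1)^d − k^d`, `d = H − 1/α`, `k < M` (default cutoff
  M = 600, recorded in the output label), then cumulated into a
  motion. `d = 0` degenerates to an ordinary stable Lévy motion. The
  kernel is proportional to the continuous moving-average weights; the
  overall constant is immaterial for scale-invariant analyses and is
  left unnormalised.
* **Gain profiles.** Piecewise-constant multipliers over exact block
  boundaries; the default five-block profile (1, 3, 10, 4, 1 over
  200-sample blocks of an N = 1000 signal) is the nonstationary
  amplitude stress test.

All generators are bit-reproducible given (spec, seed); experiment
drivers derive per-realisation seeds from a single master seed via
`SeedSequence`.

## What the synthetic validation shows — and what it does not

The generators emulate stationary coloured noise and exactly
self-similar Gaussian/stable processes. They do not emulate artefacts,
nonstationarity beyond piecewise gain, finite measurement noise mixed
with deterministic structure, or the band-pass filtering applied to
the public EEG database whose file dialect the reader supports (that
filtering belongs to the source data, not the method, and is not
implemented). Passing tests therefore establishes the estimators'
mathematical properties (invariances, terminal values, undefinedness
behaviour, oracle equivalence) and their behaviour on ideal
self-similar inputs — not clinical performance on real EEG.

Problem sizes used in the validation suite are desk scale by design:
N = 1000 signals, 10–100 realisations, a 10-point reduced tolerance
grid for sweep-based checks, and brute-force oracle comparisons at
N ≤ 50. The full-scale protocol (99 H levels × 100 tolerances × 100
realisations) remains available through `run_experiment` without the
`reduced` flag.

## Known limitations

* RangeEnA at small tolerances is frequently undefined on noise-like
  signals; downstream sweeps must handle skipped fits (they do, by
  design).
* The R/S estimator is biased at short lengths and the package does not
  de-bias it; comparisons should hold N fixed.
* No multiscale (delay > 1 / coarse-grained) variants, no multichannel
  inputs, and no detrended-fluctuation or wavelet Hurst estimators.
* fLm moments beyond location are infinite for α < 2; summary
  statistics on raw fLm paths should be read accordingly.
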