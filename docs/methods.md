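# Methods

`sdmshift` reimplements, as a tested library, the complete quantitative
workflow of an invasion-risk assessment for a spreading weed: reconstructing
the invasion timeline from country-level first records, fitting and tuning a
presence–background maximum-entropy species distribution model (SDM),
quantifying niche dynamics between the native and invaded ranges in a
two-axis environmental space, and converting thresholded suitability maps
into per-ecosystem area accounts and latitudinal profiles.  All stages run
end-to-end on synthetic virtual-species data with known ground truth, which
is how the package validates itself.

## Invasion timeline

Each country's invasion year is taken to be its earliest documented record.
Records are binned into one open-ended pre-interval (before 1970 by
default) plus fixed-width intervals (10 years); a trailing partial period is
merged into the last full interval, so 1970–2023 gives five finite
intervals, the last spanning 2010–2023.  Phase segmentation uses a
spread-rate threshold (default 6 newly invaded countries per interval): the
lag phase is the maximal prefix below the rate (the open pre-interval is
always lag and excluded from the rate comparison), the spread phase the
maximal following run at or above it, and the remainder equilibrium.  The
threshold is a parameter because the underlying narrative segmentation has
no published quantitative rule; the default reproduces the lag/spread/
equilibrium boundaries (1980, 2010) implied by the documented per-interval
counts (7, 2, 6, 7, 14, 5).

## Occurrence cleaning and thinning

Cleaning drops rows without finite in-bounds WGS84 coordinates and
collapses exact duplicate coordinate pairs, reporting counts.  Spatial
thinning keeps at most one record per square cell; the kilometre cell size
is converted to a fixed angular cell (`cell_km / 111.32` degrees) anchored
at (−180°, −90°).  Within a cell the first record in input order is kept —
a deterministic, seedless rule that makes thinning idempotent and
bit-reproducible.  No projection machinery is used; at the 5 km default the
angular approximation is the same convention as common raster-based
thinning tools.

## Maximum-entropy SDM

The model is a Gibbs density over background cells,
`P(x) ∝ exp(f(x)·λ)`, fitted by minimizing the mean negative
log-likelihood of the presences plus an L1 penalty `Σ β_j |λ_j|`.  Feature
classes are the classic five: linear, quadratic, product, threshold and
hinge (L, Q, P, T, H), all mapped to [0, 1], with threshold/hinge knots at
equally spaced quantiles of the background distribution (50 by default).
Per-feature penalties follow the published MaxEnt defaults — a
class-specific base interpolated in the presence count, times the feature's
standard deviation over presences, divided by √m — scaled by the global
regularization multiplier (RM).  The tables live in
`maxent.DEFAULT_BETA_TABLES` and can be edited.

Optimization is FISTA (accelerated proximal gradient) with backtracking
line search and adaptive restart; convergence when the maximum coefficient
change drops below 1e−7, capped at 10⁴ iterations.  Restart matters: plain
FISTA oscillates near sparse solutions and can exhaust the iteration cap.
There is no intercept — the Gibbs normalization absorbs it, which is why an
all-zero coefficient vector predicts a uniform density.

Output links: `raw` (the density itself, summing to 1 over the training
background), `logistic` (`c·raw/(1+c·raw)`) and `cloglog`
(`1−exp(−c·raw)`, the default), both using `c = exp(H)` with H the entropy
of the training-background distribution.

Tuning grids RM over 0.5–4 in steps of 0.5 crossed with feature-class sets,
scoring each candidate by AICc = 2k − 2lnL + 2k(k+1)/(n−k−1), where k is
the number of non-zero coefficients, n the presence count, and lnL the sum
of log raw probabilities at presences; candidates with k ≥ n−1 get +∞.
Ties break to fewer coefficients, then larger RM (the simpler model).

Diagnostics: training AUC is the normalized Mann–Whitney statistic (ties
count ½) of presence vs background scores, and is labelled a *training*
AUC — no held-out partition is implemented.  The jackknife reports training
gain (mean presence log-probability relative to uniform) for the full
model, each single-variable model and each leave-one-out model.  Percent
contribution is permutation importance — the mean AUC drop over seeded
shuffles of one covariate across pooled rows, floored at zero and
normalized to 100 — rather than the path-gain accounting of the original
MaxEnt implementation; permutation importance is well defined for any
penalized fit, the path accounting is tied to a particular optimizer
trajectory.  Response curves sweep one covariate over its training range
with the others held at their background means.

## Niche dynamics (COUE framework)

The two ranges are compared on the first two principal components of the
standardized, pooled background environments.  Each range's occupancy on a
100×100 grid over the (10%-padded) score bounds is a Gaussian kernel
density of its occurrence scores with per-axis Silverman bandwidths,
divided by the kernel density of its own background — the
availability-corrected occupancy — renormalized to sum to 1.  Kernels are
truncated at 5 bandwidths so the grids contain exact zeros; untruncated
Gaussian kernels are nowhere zero and would make every "cells where the
other range's occupancy is zero" quantity degenerate.  The background mask
used for the corrected surface keeps cells above 1e−3 of the maximum
background density; the full kernel support defines the range's
environmental envelope.

Schoener's overlap D = 1 − ½·Σ|z₁ − z₂| is computed on the corrected
occupancies.  The equivalency test re-splits the pooled occurrences into
the original sample sizes (100 iterations by default) and reports the
lower-tail p-value (k+1)/(reps+1); the similarity test relocates the
invaded range's occupancy to a random cell of its background mask (centroid
translation with wraparound) and reports the upper tail.  Both are exact
multiples of 1/(reps+1) by construction.

Expansion, stability and unfilling are computed on the **uncorrected**
occurrence densities restricted to the intersection of the two
environmental envelopes, with each surface renormalized there: expansion is
invaded mass where native occupancy is zero, stability its complement, and
unfilling native mass where invaded occupancy is zero.  Using the corrected
surfaces here (available via `use_corrected=True`) is numerically fragile:
the correction divides by background density exactly where expansion
happens — rare environments — and the resulting ratio noise can swamp the
signal.  The uncorrected-within-intersection convention matches the
reference R implementation of these indices.

## Suitability thresholding and area accounting

Suitability is cut at a fixed threshold (0.23 by default, treated as a
required user parameter, with the boundary value itself classed as
non-suitable per the closed upper bound of the non-suitable interval; a
strictness flag flips this for sensitivity analysis).  Cell areas are
spherical: `R²·Δλ·(sin φ_top − sin φ_bottom)` with R = 6371 km; the global
sum matches 4πR² to well under 0.5% at 5-arc-minute resolution.

Ecosystem accounting is fraction-weighted, not dominant-type: each cell
contributes `cell_area × fraction` of forest/cropland/grassland/urban to
the ecosystem's total, and the same restricted to suitable cells to its
suitable-area figure.  Land-use states aggregate by a configurable mapping
defaulting to the LUH2 names (primf, secdf → forest; the five crop states →
cropland; range, pastr → grassland; urban → urban).  Area tables carry both
raw km² and 10⁴ km² columns because published tables print the latter while
running text often prints the former.

Latitudinal profiles average suitability in half-open 0.5° bands weighted
by `cell_area × fraction`, fit a degree-2 polynomial per hemisphere by
least squares (on a centered/scaled abscissa) with a pointwise 95%
confidence band, and report the peak latitude as the continuous argmax of
the fitted curve over the observed band span — giving 0.1° precision from
0.5° bands.  A fitted curve whose total variation is below 1e−6 is treated
as flat and its peak reported as undefined.

## Synthetic data

The generators are pure functions of their seeds and define the study
conditions for the test suite:

* **Climate stack** — each layer is 0.6 × a latitudinal gradient plus 0.4 ×
  Gaussian noise smoothed over 2 cells, min-max rescaled to bioclim-like
  ranges (−10…30 °C, 0…3000 mm, …).  Default world: 50×50 half-degree
  cells spanning latitudes −12.5°…12.5°, so both hemispheres are exercised.
* **Virtual species** — suitability is a product of per-covariate Gaussians.
  The canonical species places optima at the 0.75 quantile of every
  covariate (a coherent position on the shared climate gradient) with
  breadths of 8% of each covariate's span.  Presences are drawn with
  probability proportional to suitability × cell area (or by Bernoulli
  acceptance) and jittered uniformly within cells, so thinning tests see
  multiple points per cell.
* **Niche-shift scenario** — the grid splits into a western (native) and
  eastern (invaded) extent; the invaded optima are displaced by the
  programmed magnitude in units of the realized-niche standard deviation
  (the suitability-weighted SD of each covariate over occupied cells),
  toward the side of the climate envelope with more room.  This unit keeps
  shifts of 0–4 inside analog environments, where the COUE indices are
  defined; displacement in grid-level SD units would exit the attainable
  envelope entirely (the envelope is only ~4 grid SDs wide) and the
  programmed expansion would be excluded as non-analog climate.
* **Land use** — per-cell state compositions from a symmetric Dirichlet over
  twelve LUH2-style states; two (primn, secdn) are left unmapped so
  per-cell ecosystem sums stay below 1, as in real fraction layers.
* **Timeline** — first-record years follow a logistic cumulative curve
  (midpoint 1995, rate 0.15 by default) normalized to the year window, with
  seeded integer jitter.

What the synthetic data does *not* emulate: the covariance structure of
real bioclim variables beyond a shared gradient plus autocorrelated noise,
sampling bias in occurrence records, spatial autocorrelation of residual
suitability, and climate-model structure for future scenarios.  Passing
tests therefore demonstrate the correctness and calibration of the
*methods*, not the realism of any particular ecological conclusion.

## Simulation sizes and calibration checks

The self-checks run at desk scale, chosen once: parameter recovery uses 20
replicates of 200 presences on a 50×50 world (the fitted response-curve
peak must land within 5% of the covariate range in ≥90% of replicates);
the null calibration of the equivalency test uses 200 simulations of two
independent 100-presence draws from one suitability surface over one
shared extent, at 99 permutations each — the empirical rejection rate at
α = 0.05 must lie in [0.01, 0.12] (measured: 0.05).  The shared extent is
essential: with disjoint extents the pooled re-split is not exchangeable
(the two ranges have different availability) and the test is genuinely
liberal — that situation is a true difference in available environments,
not a calibration failure.

## Numerical choices and degenerate inputs

* Pearson correlations for covariate filtering use pairwise-complete
  observations; a zero-variance layer correlates 0 with everything and is
  flagged rather than fatal.
* Cell containment is half-open `[west, east) × (south, north]`; a point on
  a shared edge belongs to exactly one cell.
* Constant covariates contribute only their (constant) linear feature, with
  a warning.
* Raster round-trips: ESRI ASCII grids are written at full float precision
  (`%.17g`) and reproduce exactly; GeoTIFF I/O goes through `tifffile` with
  the standard ModelPixelScale/ModelTiepoint georeferencing tags.
* Ties in AICc selection break to fewer coefficients, then larger RM;
  candidate order never matters.
* All randomness flows through explicit integer seeds into
  `numpy.random.default_rng`; every generator and permutation test is
  bit-reproducible.

## Known limitations

* Training AUC only; no cross-validation partitioning (checkerboard or
  spatial blocks) and no extrapolation/clamping diagnostics (MESS maps).
* No reprojection or resampling: all rasters must share one lattice, and a
  mismatch is an error, not a silent fix.
* The environment space is strictly two principal components; no other
  ordination is offered.
* Country-level attribution of gains and losses would require political
  boundary polygons and is out of scope.
* The suitability cutoff (0.23) is accepted as given; the package does not
  re-derive a thresholding rule.
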