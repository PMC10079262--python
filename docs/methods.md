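# Methods

This note records the models behind `celltracks`, the defaults that
matter, and the numerical and design choices made where more than one
reasonable option existed.

## Data model and analysis scales

A track is a strictly time-ordered sequence of positions of one cell;
datasets are ordered collections of tracks sharing dimensionality (2 or
3). Coordinates are stored exactly as read — units (micrometers and
minutes by convention) are metadata, never converted. Tracks iterate in
lexicographic id order, so every downstream statistic is deterministic
regardless of file row order.

All analysis scales are decompositions into contiguous *subtracks*, whose
length always counts steps:

- **cell-based**: one value per whole track. Simple, but biased when
  tracks have very different lengths — long tracks are underweighted per
  step.
- **step-based**: one value per subtrack of a fixed number of steps;
  with maximal overlap a track with $n$ steps yields $n-\ell+1$ subtracks
  of $\ell$ steps, with no overlap $\lfloor n/\ell \rfloor$.
- **staggered**: every contiguous subtrack $[i,j]$, a triangular matrix
  of $n(n+1)/2$ values per track, used to localize behaviour within a
  track.

Duplicate timestamps within a track are an error, not averaged: they
almost always signal tracking faults and should be inspected, not
repaired silently.

## Quality control

**Double tracking.** One cell tracked as two near-identical tracks shows
up as a pair with a jointly small minimum distance (over shared
timepoints; timestamps match within $10^{-6}\times$ the median step
duration) and a small angle between overall displacement vectors. Pairs
without temporal overlap are omitted, with a count: positions at
different times carry no co-tracking signal. The rank-product helper
orders pairs by the product of their distance and angle ranks; the
package deliberately does not pick an automatic threshold — the
distance–angle table is designed for inspection.

**Gaps.** Steps whose duration deviates from the per-track median by more
than `tolerance` × median (default 0.5, i.e. anything outside
[0.5×, 1.5×] the median interval) are flagged. Repair modes: `drop` the
track, `split` it at flagged steps (ids suffixed `.1`, `.2`, … in
temporal order, collision-checked), or linearly `interpolate` onto the
track's modal-interval grid.

**Drift.** Estimated globally as (sum of all step vectors) / (sum of all
step durations) — a single velocity for the dataset, because per-track
"drift" is indistinguishable from genuine directed motion. Correction
subtracts $v\,(t - t_\text{first})$ per track; re-estimating on corrected
data returns zero to machine precision. This mean-step-velocity estimator
is this package's choice of drift model; registration-based correction is
out of scope.

**Interpolation** is linear (exact on the original timestamps) or cubic
spline (≥ 4 observations); extrapolation beyond a track's time span is
always an error.

## Measures and undefined values

Measures are plain functions `Track -> float`; any user function with
that contract works everywhere a built-in does (feature matrices, lag
aggregation, filtering). Undefined results — zero-length tracks,
zero-duration speeds, turning angles at a zero step — are IEEE NaN,
a deliberate distinct marker: silently dropping or zeroing undefined
entries is a known source of bias. Aggregations exclude NaNs but report
the count actually used; feature matrices record which tracks carried
undefined entries rather than imputing.

Angles are computed with `atan2(||u x v||, u.v)`, stable near 0° and
180° where the arccos form loses precision, and reported in degrees. The
gyration tensor for asphericity uses unweighted observation positions
(the literature convention; weighting by interval length would be an
alternative for very uneven sampling).

MSD/autocorrelation aggregation defaults to maximally overlapping
subtracks — more data per lag, at the price of correlated summands — and
reports `n` per lag always; non-overlapping mode exists for
independence-sensitive uses (the test suite uses it whenever a standard
error is computed from `var/n`). Lag-to-time conversion requires a
uniform step duration; mixed-interval datasets must be gap-repaired
first, and the aggregator raises otherwise rather than guessing.

## Hotelling's T²

The one-sample test on pooled step vectors:
$T^2 = n\bar{s}^\top S^{-1}\bar{s}$, $F = T^2(n-p)/(p(n-1))$ against
$F(p, n-p)$. The $(1-\alpha)$ confidence region of the mean step has
half-axes along the eigenvectors of $S$ scaled by
$\sqrt{\lambda_i\, p(n-1) F_{1-\alpha}/(n(n-p))}$.

Consecutive steps of one cell are autocorrelated, which inflates the
type-I error of the pooled test on persistent walkers. `step_spacing=k`
keeps every $(k+1)$-th step per track to decorrelate; the default is 0
(all steps) with this caveat, and a per-track-means variant is available.
3D data can be tested on an axis subset (`dim_select`), matching the
common practice of projecting to xy. On truly independent steps the test
is calibrated: simulated type-I error at α = 0.05 is within 0.05 ± 0.02
over 1000 replicates (the acceptance script recomputes this).

Useful baselines under isotropy: mean turning angle and mean angle to any
fixed direction or distant point are 90°; the mean angle between a 3D
step and a fixed plane is $180/\pi\,(\pi/2 - 1) \approx 32.70°$.
Deviations of these per distance bin localize drift and boundary
artifacts — note that constrained motion at a boundary *flattens* angles
to that boundary (below 32.70°), since crossing steps lose
normal-component magnitude.

## Feature maps and clustering

Feature matrices default to per-column standardization (mean 0, sd 1;
constant columns centered with recorded zero scale) because typical
feature sets mix units — μm/min, degrees, μm². PCA uses a fixed sign
convention (largest-magnitude loading positive) and is therefore
bit-reproducible; MDS is classical Torgerson scaling via
eigendecomposition — deterministic, and exactly equivalent to PCA for
Euclidean feature distances — rather than stress-majorization, which is
initialization-dependent. Clustering is average-linkage agglomeration
(deterministic) or k-means with a recorded seed and restart count.
Stochastic embeddings (UMAP/t-SNE) are intentionally not wrapped; the
feature matrix exports cleanly if they are wanted.

## Simulators

**Brownian**: independent per-axis Gaussian increments of standard
deviation σ, optional constant drift per step. MSD per lag $\ell$ is
$d\,\sigma^2 \ell$.

**Bootstrap**: step lengths and turning angles drawn independently with
replacement from a reference dataset's pooled empirical distributions;
each step is the previous direction rotated by the sampled angle (in 3D
about a uniformly random axis normal to the current direction) and scaled
to the sampled length. Reproduces single-step statistics of the
reference without assuming a parametric model; it does *not* reproduce
longer-range correlations (e.g. persistence across several steps beyond
what the angle distribution encodes).

**Beauchemin walk**: alternating straight "free" runs (speed
`v_free`, duration `t_free`, direction uniform on the sphere/circle) and
stationary pauses (`t_pause`); turning happens at pause end. Defaults
`v_free = 18.8` μm/min, `t_free = 2` min, `t_pause = 0.5` min follow the
published intravital T-cell parameterization; they are defaults, not
constants. The observed track samples the continuous piecewise-linear
path exactly at every `delta_t`. By default the process starts uniformly
within its free+pause cycle, making observed statistics time-stationary;
`stationary=False` starts at a run boundary, which aligns observation
intervals with phases (useful for exact step-length constructions).
Directional bias adds `p_bias · bias_dir` to each uniform direction and
renormalizes — exactly uniform at 0, monotone in `p_bias`; this is one
concrete, simple bias mechanism among several possible. The long-run MSD
slope is $v^2 t_\mathrm{free}^2/(t_\mathrm{free}+t_\mathrm{pause})$ per
unit time in any dimension (motility coefficient
$M = v^2 t_\mathrm{free}^2 / (2d(t_\mathrm{free}+t_\mathrm{pause}))$),
approached for lags well beyond the cycle time.

All simulators are bit-reproducible from their seed; replicate sets
expand one root seed into per-track substreams (numpy `SeedSequence`), so
results are independent of execution order.

## MSD model fitting

`fit_msd` least-squares fits a model MSD to an empirical curve over lags
up to `max_fit_lag` — long lags should be excluded because a limited
imaging window biases the empirical MSD there. Lags are weighted equally
by default; inverse-variance weighting (`n/var` per lag) is available
since long-lag means pool few subtracks.

- Brownian: one parameter, a straight line through the origin
  (slope = $2dD$); closed-form solution.
- Beauchemin: model MSD by forward simulation with common random numbers
  (fixed per-evaluation seeds make the objective deterministic), free
  parameters any subset of (`v_free`, `t_free`, `t_pause`) optimized by
  Nelder–Mead. When only `v_free` is free the trajectory scales linearly
  in it, so MSD scales as $v^2$: the fit reduces to one simulation at the
  reference speed plus a closed-form scale estimate — exact and fast.
  An asymptotic closed-form option
  ($\mathrm{MSD}(t) \approx$ slope $\cdot\,(t - t_\mathrm{free}/3)$,
  clipped at zero) is provided for long-lag fits; it is inaccurate at
  lags comparable to the cycle time and documented as such.

## Synthetic example datasets

The fixture generator emulates, at trajectory level, a three-class
imaging experiment: fast fairly straight unbiased walkers
(`tcell_like`: v 18.8 μm/min, runs 2 min, pauses 0.5 min), slower cells
with more turning (`bcell_like`: v 6.5, runs 0.8, pauses 0.7), and
directionally biased migrators (`neutrophil_like`: v 14, bias strength
1.0 toward (1, −1)). Defaults — 70 tracks per class, 40 observations at
0.5-min intervals, 0.5 μm Gaussian localization noise, origins uniform
over a 400 μm field of view — mirror a typical two-photon recording, and
the effect sizes were chosen once to be detectable at that sample size
without being trivial. The generator records all class parameters in its
metadata. It does not emulate z-anisotropy, fluorophore blinking,
segmentation error or cell–cell exclusion: green tests demonstrate
correctness of the analysis chain on data with known ground truth, not
robustness to every real-world imaging pathology.

`inject_duplicate` reproduces the double-tracking artifact by appending a
Gaussian-perturbed copy of one track with the same timestamps; with noise
far above the track extent the pair is no longer geometrically linked and
detection fails, which the tests document as the method's breakdown
point.

## Problem sizes and tolerances

Statistical checks in the tests and acceptance script use sizes at which
the relevant asymptotics hold comfortably: ~10⁴ pooled steps for angle
baselines and diffusion slopes, 1000 replicates for test calibration, 100
datasets for duplicate-recovery rates, 100 tracks of 10³ observations for
the Beauchemin long-run slope (which needs lags ≫ the 2.5-min cycle).
Sampled quantities are asserted within 3 standard errors computed on
independent units (tracks, or non-overlapping subtracks); exact
identities (subtrack counts, balanced-design $T^2 = 0$, straight-mover
MSD) are asserted to machine precision.

## Known limitations

- The pooled Hotelling test assumes independent steps; use
  `step_spacing` or per-track means for persistent walkers.
- Gap interpolation is linear; strongly curved paths through long gaps
  are straightened.
- The bootstrap simulator treats step length and turning angle as
  independent draws, discarding any speed–turning coupling present in
  the reference.
- Beauchemin fitting by forward simulation inherits simulation noise in
  the objective away from the `v_free`-only fast path; the common random
  numbers keep it deterministic but not smooth to arbitrary precision.
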