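# Methods

`bathysdm` re-creates, at desk scale, the workflow by which sparse
singlebeam (SBES) bathymetry is turned into demersal-fish distribution
models and compared against models built on full-coverage (MBES-style)
bathymetry.  This note documents the models, the defaults, and the design
choices that were genuinely open.

## Synthetic study system

The generator (`bathysdm.synth`) emulates a narrow continental-shelf strip:

* **Seafloor.**  depth(x, y) = trend + Z(x, y) + nugget noise, with the
  trend an across-shore ramp (default 20 m at the coast, gradient
  0.022 m/m, i.e. ~130 m at 5 km offshore) and Z a zero-mean stationary
  Gaussian random field with Gaussian covariance
  C(h) = sill * exp(-3 (h/a)^2).  `a` is the *effective range* (the
  distance at which the semivariogram reaches ~95% of the sill), the form
  under which survey-scale ranges of a few hundred metres are normally
  quoted; simulation and variogram fitting share this parameterisation so
  recovery tests are meaningful.  Geometric anisotropy is applied by
  stretching the minor-axis lag component by 1/ratio; the default major
  axis is coast-parallel (azimuth 90 deg) with ratio 0.5, sill 4 m^2 and
  major range 600 m, inside the 428–720 m window typical of shelf
  bathymetry at this scale.  Fields are simulated exactly by FFT circulant
  embedding; the torus is padded by two ranges so the Gaussian covariance
  has decayed to ~1e-5 of the sill at wrap-around, and eigenvalues are
  clipped at zero only when the negative mass is numerically negligible
  (otherwise the scenario is rejected).
* **Survey.**  Coast-parallel transects every 500 m across-shore (edges
  inclusive), soundings every 40 m along track in serpentine order,
  timestamps from a constant vessel speed (5 m/s).  Recorded depth =
  bilinear DEM depth + (tide − datum offset) + N(0, 0.3 m) noise, with
  spike errors (±~30 m, rate configurable) injected at random.  The tide
  is a single sinusoid (default 1 m amplitude, 12.42 h period, phase from
  the seed) — enough to exercise the correction path; real tidal mixtures
  of constituents are deliberately not modelled.  The 0.30 m datum offset
  mimics reducing from chart datum to a land-height datum.
* **Stations and species.**  Stations are uniform with a minimum
  separation (default n = 500, 200 m) by rejection sampling — no
  stratification, since camera-deployment designs vary.  Occurrence is
  Bernoulli with
  logit p = b0 − beta_depth ((depth − depth_opt)/depth_tol)^2 +
  Σ beta_l z_l, the z_l standardized terrain layers.  A target prevalence,
  when given, calibrates b0 by bisection on the realized stations (to
  0.002, well inside the ±0.02 contract).  The default pair of species is
  a deep-water specialist (beta_depth = 6, depth_opt near the 90th depth
  percentile, tolerance 15 m, prevalence 0.25) and a no-signal generalist
  at prevalence 0.7 — the two ends of the prevalence/model-skill spectrum
  that presence/absence modelling typically shows.

What the generator does *not* emulate: echo-envelope physics, multibeam
swath geometry, real micro-relief (reef structure, sand waves), detection
error in the video stations, and spatial sampling bias.  Green tests
therefore demonstrate that the pipeline recovers the structure it assumes,
not that it would perform identically on real reef bathymetry — in
particular real fine-scale relief makes fine-resolution derivatives far
richer than a smooth Gaussian field can.

## Soundings QC

Order: block averaging → tide correction → despiking (the order is
recorded in a provenance log and switchable).  Averaging happens in the
depth domain — raw-waveform averaging is out of scope — with trailing
blocks kept when at least half full.  Tide correction subtracts
(interpolated tide − datum offset) and is exactly invertible.

Despiking replaces manual editing with a Hampel-style rule: a record is
dropped when its deviation from the running median (window 5) exceeds
6 × a robust noise scale.  The scale is estimated per transect as
1.4826 × MAD of first differences / √2, floored at 0.01 m.  Two cheaper
choices fail quietly: a MAD computed inside the 5-point window is so
variable that several percent of clean records exceed six times it, and a
pooled MAD of the running-median residuals is dragged toward zero because
a locally monotone (trending) track makes the centre point *be* the
median.  Differencing cancels the smooth seafloor signal and the median
makes the estimate immune to the spikes being hunted; with the defaults
the filter removes essentially all ±15–45 m spikes at a ~0% false-removal
rate and is idempotent.  The skewness gate (adjusted Fisher–Pearson, flag
at |skew| > 1) only advises a transformation; it never changes data.

## Variogram estimation and fitting

The empirical semivariogram is the method-of-moments estimator binned by
lag (and by azimuth ± tolerance for directional variograms).  The only
theoretical model is the Gaussian model above; fitting is weighted least
squares with Cressie weights N(h)/γ_model(h)^2.

Two practical points matter on survey data:

* **Detrending.**  Shelf depths are trend-dominated; the raw-depth
  variogram keeps climbing with the squared ramp and the fitted range runs
  to the bound.  The pipeline therefore estimates the variogram on OLS
  degree-1 residuals by default (configurable 0/1/2); the kriging
  predictor itself handles the trend through its universal-kriging basis.
  The `empirical_variogram` operation keeps raw depths as its default —
  detrending is an explicit argument.
* **Anisotropy.**  Independent per-direction range fits are unstable under
  transect geometry (the across-track direction may have only a few
  populated lags).  Nugget and sill are therefore fixed at the
  omnidirectional fit and a single joint WLS fit of (major range, angle,
  ratio) is made over *all* directional bins, with multistart over the
  observed directions; a fit that runs to the lag-span bound falls back to
  the isotropic model with a warning.  On scattered samples of a ratio-0.5
  field this recovers the ratio within ±0.15 and the axis within ~±30 deg.
  The fit is additionally constrained so the omnidirectional range lies
  between the minor and major ranges (true for geometric anisotropy),
  which excludes degenerate huge-range/sliver-ratio optima.  Under
  perfectly regular transect geometry the cross-track directions have no
  sub-range lags, so the ratio is only weakly identified there (recovered
  within roughly a factor of two); kriging accuracy is insensitive to
  this.

## Interpolators

All three families are neighborhood-local (k-d tree search, default 30–150
neighbors), since global solves are infeasible at 10^4 soundings, and all
local systems are solved in batch with a least-squares fallback for
singular neighborhoods.

* **IDW** — weights d^(−p); weights are computed in the log domain
  normalised by the nearest distance, so powers up to the
  nearest-neighbor-limit regime (p ≈ 50) are stable.  Exact-hit rule:
  queries within 1e-9 m of a datum return that datum.
* **RBF** — local collocation with a linear polynomial part and side
  conditions, basis either multiquadric √(r² + δ²) or the completely
  regularized spline −[ln ρ + E1(ρ) + γ_E], ρ = (δr/2)².  The
  "robustness" parameter is interpreted as a smoothing ridge on the kernel
  diagonal; its sign follows the basis's conditional definiteness
  (negative for the multiquadric, positive for the CRS), which is the
  direction in which the ridge actually damps the interpolant — applied
  with the wrong sign it *amplifies* noise.  δ and the ridge are chosen by
  LOOCV grid search (on a ≤2000-point subsample, seeded), ties toward the
  smallest δ then the smallest ridge, with differences under 1e-9 m
  treated as ties.
* **Kriging** — OK/UK1/UK2 via the augmented semivariogram system
  [Γ F; Fᵀ 0][λ; μ] = [γ0; f0], prediction variance γ0ᵀλ + f0ᵀμ, with the
  monomial basis on locally centred/scaled coordinates and a 1e-10
  diagonal jitter (the Gaussian model is notoriously ill-conditioned).
  Γ's diagonal is 0; the nugget acts between distinct points, so the
  predictor honours data exactly when the nugget is zero.  Anisotropy is
  applied by rotating/scaling lags before evaluating γ; the hot path works
  on squared effective distances via a batched Gram-matrix product.

**Selection** follows the cross-validation convention for this workflow:
LOOCV (variogram *not* refitted per fold, matching standard geostatistical
practice and keeping the cost O(n·k³)); IDW/RBF ranked by RMSE, kriging by
|ASE − RMSE| (the calibration gap between the average kriging standard
error and the realized error); families compete on raw RMSE.

## Terrain derivatives

Smooth once at native resolution (5×5 Gaussian, σ = 1 cell — the kernel
width is stated in the source workflow, σ is not; the kernel is
renormalised over valid cells so nodata and edges do not bleed), then
bilinear-resample to each analysis resolution, then 3×3 derivatives:
Horn slope/aspect (aspect as northness/eastness), window SD (sample, n−1),
TRI, TPI, roughness, and mean curvature −(a+b) from an exact least-squares
quadratic fit.  Up/down-sensitive derivatives are computed on elevation
(−depth), so "concave = depression = negative curvature" holds.  Flat
cells take NS = WE = 0 (rather than nodata) to keep feature matrices
complete, with gradients under 1e-12 treated as flat.  The default ladder
is native cell × {1, 3, 5, 8} — at the 25 m desk-scale native cell this is
25/75/125/200 m, the analogue of a 3/9/15/25 m ladder on 3 m data.

## Surface agreement

Cell-centre distance to the nearest track line partitions the map into
half-open bands ((0,100], (100,200], (200,300], (300,400] m by default);
per band the interpolated and reference pixels are compared by Pearson r
(two-sided t-test p) and OLS of *reference on predicted* (the direction is
a documented convention; the literature is agnostic).  The p-values ignore
spatial autocorrelation and are therefore optimistic — a known limitation,
not corrected here.

## Distribution models

Random-forest classifiers (500 trees, √p candidate features, no class
weights) per species × bathymetry source.  Evaluation: a stratified 70/30
holdout (residuals = observed − predicted probability, positive =
underprediction) and stratified 5-fold cross-validated AUC over all
stations; sources are compared by a Welch two-sample t-test on fold AUCs
(folds are split independently per source, so a paired test would be
unjustified).  Variable importance is permutation importance on the
held-out data (mean AUC drop, 10 permutations, seeded) — chosen over
impurity importance because multi-scale terrain features are strongly
correlated and impurity measures are biased there; importance rankings
depend on this choice.  Partial dependence clamps one feature to a
2.5–97.5% quantile grid and averages the predicted probability.

## Numerical choices and problem sizes

Exact-hit distance 1e-9 m; kriging jitter 1e-10; singular local systems
bisected out of the batch and solved by pseudo-inverse (flagged);
LOOCV subsample cap 2000 points for RBF optimisation; prevalence
calibration tolerance 0.002; flat-gradient floor 1e-12.

The repeated-seed experiments in the test suite and the acceptance script
run on a scaled shelf — 8 × 3 km (6 × 2.5 km for the model-comparison
experiment) at a 25 m native cell, with 300 stations at 100 m separation —
chosen so the full multi-seed designs remain comfortable on a single CPU
while keeping every structural feature of the full-size scenario (same
anisotropy, noise, transect geometry, prevalence regime).  The full-size
defaults (35 × 5 km, 500 stations) remain the generator's defaults.

## Known limitations

* The Gaussian-covariance world is smooth; artefact patterns on real
  track-line data (the motivation for smoothing) are milder here.
* No sound-speed/heave/draft corrections; no co-kriging or
  splines-in-tension; no spatial blocking in the cross-validation (plain
  random folds, as in standard practice for this workflow).
* Band-comparison p-values are optimistic (no effective-sample-size
  correction).
* UK2 with few neighbors on near-collinear transect neighborhoods is
  ill-posed often enough that its LOOCV error can be large; it is retained
  because its poor behaviour is itself part of the expected method
  ranking.
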