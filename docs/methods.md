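# Methods

This note documents the models, algorithms and numerical choices behind
`eemtopo`, in the order data flows through the package.

## 1. Surfaces and units

A scan is a rectangular grid of heights with a validity mask. Heights
and lateral spacings are micrometres everywhere inside the package;
unit conversion happens only in the file readers. Grids are row-major
with (0, 0) at the top-left corner and y increasing downward. Scans are
accepted for analysis when at least 95 % of grid points were measured
(inclusive threshold); non-measured points are carried as a mask and
never enter numeric reductions.

## 2. Synthetic bone surfaces

The generator is the package's test bed: it produces surfaces with the
statistical structure the downstream analysis assumes, not a
tribological simulation of eraser–bone contact.

**Base field.** Spectral synthesis of a stationary Gaussian field with
squared-exponential correlation (default correlation length 1.5 µm on a
160 x 160 grid at 0.4 µm spacing), band-limited by removing content the
large-scale L-filter would classify as form (nesting index 8 µm). The
generator emits the roughness band directly, so for synthetic studies
the texture parameters are computed on (lightly noised) generator
output; the full S-/L-filter chain exists for ingesting instrument
scans and is validated against its own transfer-function oracles.

**Height marginal.** The field is pushed through the quantile function
of a *two-process* marginal (a Gaussian copula): a tight Gaussian
plateau core (scale 0.10 before Sa-rescaling) carrying 45 % of the
material, an exponential asperity tail above the top 20 %, and an
exponential valley tail below the bottom 35 %; the result is rescaled
so the realized Sa equals the target (default 0.60 µm). This marginal
is what makes the upper material ratio realistic: lamellar bone
presents a load-bearing plateau with residue peaks above and pores
below, and such surfaces sit near Smrk1 ≈ 18–20 % with a small
scan-to-scan spread. A purely Gaussian marginal pins Smrk1 near 10 %
and — this is a mathematical property of the Sk secant construction,
not a tuning issue — *cannot* respond to plateau truncation with an
Smrk1 increase: truncating above the core-line intercept leaves the
count of points above it unchanged, and truncating below it empties the
peak region entirely.

**Optional features.** V-profile cut marks (depth/width/orientation/
count) and raised Gaussian residue blobs can be superimposed; a dropout
fraction (≤ 0.05, so generated scans pass QC) marks points non-measured.

## 3. The eraser-wear operator

Wear is modelled as four components, applied in order:

1. **Asperity truncation** — heights above the (1 − q) material-ratio
   height are moved toward it, keeping a `compression` fraction
   (default 0.2) of their excursion; `hard_clip` sets them exactly to
   the cut. Default q = 0.05.
2. **Plateau polish** — micro-relief within the plateau percentile band
   (35th–80th) is shrunk toward its centre by a `polish` fraction. By
   default polish = 2q (capped at 0.6), so one knob scales the whole
   wear intensity. Physically this is the eraser-dragged particle film
   smoothing the load-bearing surface; statistically it is what flattens
   the core of the Abbott curve and moves the core-line intercept down,
   which is how Smrk1 rises under wear.
3. **Micro-striations** — parallel V-grooves along the stroke direction
   (default depth 0.01 µm — superficial relative to Sa, as the traces
   appear in micrographs — width 1.2 µm, spacing 4 µm, seeded phase).
4. **Remeasurement noise** — i.i.d. Gaussian noise (default 0.005 µm)
   representing repositioning and instrument noise; the generator's
   "before" scans carry the same noise. An optional lateral offset
   shifts the content (reflect-filled at the exposed margin) and is
   recorded in the origin offset, for exercising pair registration.

With the default marginal, the operator is monotone in q for Smrk1
(non-decreasing) and Sa (non-increasing) while the cut stays above the
plateau, i.e. for q up to the asperity mass fraction (~0.2). Beyond
that the cut enters the plateau itself and the Smrk1 response of the
secant algorithm is no longer monotone — no truncation-type operator
can avoid this — so the defaults and the property tests stay in
q ∈ [0, 0.2]. At the default strength the operator yields an Smrk1
after/before ratio of ≈ 1.02 with Sa ratio ≈ 0.97–0.99 on generator
output. A known limitation: the surface-level Spc response is much
stronger than on real bone (compression scales summit curvature by the
compression factor directly), so Spc conclusions should rest on the
model-level simulator or real scans.

## 4. Pre-processing chain

* **Leveling** — least-squares plane over measured points; requires
  three non-collinear points.
* **Isolated outlier removal** — points deviating from their 3 x 3
  neighborhood median by more than k·MAD (k = 5/3/2 for
  soft/normal/strong) are flagged; only flags with no flagged
  8-neighbor are invalidated (adjacent spikes are real topography).
  When the plain MAD degenerates (locally monotone surfaces have mostly
  zero deviations) the median absolute nonzero deviation sets the
  scale. Invalid points are filled by biharmonic inpainting.
* **Pair alignment** — integer-pixel cross-correlation of the zero-mean
  surfaces with parabolic sub-pixel refinement for the reported offset;
  cropping to the intersection happens at integer pixels. Known offsets
  can be supplied (the study's offsets were set manually). Pairs whose
  retained overlap falls below `min_overlap` (default 0.25; no numeric
  threshold is documented for the removed pair, so this is a package
  choice) are returned as rejection records, not silently dropped.
* **Robust Gaussian regression filter** — at every pixel a quadratic
  polynomial is fitted under a Gaussian weight, implemented as moment
  convolutions (FFT) plus a vectorized 6 x 6 solve, so the cost is a
  handful of FFTs per iteration. The weight scale is
  s = sqrt(2x*)/(2π) · λc with (1 + x*)e^(−x*) = ½
  (x* ≈ 1.67835), which gives the second-order smoother exactly 50 %
  transmission at the nesting index λc; the transfer function is
  T(k) = (1 + s²k²/2)·exp(−s²k²/2). Robust iteration reweights
  MAD-scaled residuals with the Tukey biweight (c = 4.685) until the
  smooth part changes by < 1e-6 of the height range or 20 passes.
  Moments are accumulated over available support only, which
  renormalizes the kernel at borders — no data is discarded.
* **S-L surface** — S-filter at 0.8 µm (keep the smooth part), then
  L-filter at 0.008 mm = 8 µm (keep the residual), then a final
  re-level to zero mean (the robust L-filter tracks the plateau of a
  skewed surface and leaves a small offset). 0.008 mm is unusually
  small for an L-filter and may be a typo for 0.8 mm in the source
  protocol; both are plain arguments, the default follows the printed
  value.

## 5. ISO 25178 parameters

* **Sa** — mean |z − mean(z)| over measured points.
* **Material ratio curve** — empirical Abbott–Firestone curve,
  percentage of surface at or above each level, pinned to 0 %/100 % at
  the extremes.
* **Smrk1** — Sk-family upper material ratio: a 40 %-wide secant window
  slides along the curve (0.1 % steps); the least-steep secant defines
  the equivalent core line; Smrk1 is the material ratio of the surface
  at the line's height at 0 % material ratio. Degenerate flat surfaces
  raise an error. Verified against an independently coded brute-force
  secant search to 0.1 %.
* **Hill segmentation** — watershed on the inverted surface, seeded at
  h-maxima; basins are then Wolf-pruned by a persistence-style merge:
  adjacent-basin saddles are visited from the highest down and basins
  merge when the lower summit stands less than the pruning threshold
  (default 5 % of the height range — the common metrology-software
  default, as the source protocol names only "standard default
  settings") above the saddle. The h-maxima pass alone is insufficient:
  it never merges equal-height summits across a shallow saddle.
* **Sha** — mean cross-sectional area, at the cut height of the 10 %
  material ratio (configurable; the appropriate cut is an open question
  in the source protocol), over hills whose cross-section is non-empty
  and touches no boundary pixel ("closed"). A hill's *closedness* is
  evaluated at the cut height: a watershed basin always reaches the
  boundary on an open field, so boundary contact of the full basin
  would leave no closed hills at all.
* **Spc** — −½ × mean finite-difference Laplacian over the summits of
  the pruned hills, boundary summits excluded.
* Undefined parameters (no closed hills, no interior summits, flat
  surface) propagate as NaN markers, never as zeros, and such records
  are excluded from modelling with the exclusion counted in the run log.

## 6. Force traces and spectra

Contact events are local maxima above 0.5 N with a minimum separation
of 0.3 s and prominence of 0.2 N (the separation and prominence make
peak-finding well-posed at the 10 Hz sampling rate; only the threshold
is prescribed). Summaries are mean/SD of peak forces and the event
rate; comparisons are Kruskal–Wallis across groups and, for two groups,
a two-sided pooled-variance t-test (df = n1 + n2 − 2; 6-vs-6 areas give
df = 10), plus Pearson correlations for paired covariates. The trace
generator places Gaussian pulses (FWHM 0.25 s) on a jittered ~1.2 s
rhythm with maxima drawn from the target normal, snapped to the sample
grid so the drawn amplitude is the sampled maximum.

Spectra are profile m/z–intensity arrays. The baseline is removed by
SNIP-style iterative clipping in LLS space (half-window 40 points);
the noise level is 1.4826·MAD of the corrected intensities in
signal-free regions. A marker's S/N is the maximum corrected intensity
within ±0.5 Da of its mass over the noise level; presence requires
S/N ≥ 6 (both configurable; neither is printed in the source protocol).
Taxon calls intersect the taxa sets of all markers found, after
excluding markers colliding with known contaminant masses; absent
markers can only broaden a call. The bundled marker table is a
synthetic stand-in: only the 1208 Da mass of COL1α2 978–990 is anchored
in the study; the other masses are placeholders to be replaced from the
marker literature.

## 7. The multivariate multilevel model

Y = XB + ZU + E with Y the n x 4 log texture parameters, X the fixed
effects (intercept, area = cut, and for M1 erasing = after), and
crossed-by-nesting random intercepts for specimen and measurement
location, each level with its own 4 x 4 covariance; residual rows are
multivariate Gaussian. At the full design n = 118 and Z is 118 x 65.

**Priors.** Fixed effects: independent Normal(0, 1) on the log scale;
responses are column-centred internally so intercept magnitudes do not
fight the prior (the stored intercept draws are un-centred). The three
covariances carry the Huang–Wand (2013) hierarchical inverse-Wishart
prior with ν = 2, A = 1, giving half-t(2) margins on the standard
deviations and near-uniform correlation priors. These choices keep
every full conditional in closed form.

**Sampler.** A blocked Gibbs sampler: B jointly (12-dimensional
normal), each random-effect block (groups sharing a scan count share
one Cholesky), then the covariances (inverse-Wishart) and the
Huang–Wand auxiliaries (inverse-gamma). Three *translation moves* per
sweep shift mass between the intercept and the specimen-level mean, the
intercept and the location-level mean, and the area effect and the
cut-area location mean — the likelihood is invariant to these shifts,
their conditionals are Gaussian under the priors, and without them the
intercept/area rows mix with split-R̂ near 1.2–3. Defaults follow the
study protocol: four chains, 2000-iteration warm-up, 1000 retained
draws per chain (4000 posterior samples); a thinning factor (default 1
in the API, 8 in the pipeline) buys effective sample size for the
slowest quantities — the specimen-level SDs, informed by only six
specimens — at ~1.8 ms per sweep. Reported quantities are flagged when
split-R̂ exceeds 1.01, and a fit is marked unusable above 1.05.

**Ratios and LOO.** After/before ratios are exp applied to the
quantiles of the erasing-coefficient draws (exp after quantiles, so the
monotone-transform identity is exact). Model comparison uses PSIS-LOO
on the pointwise conditional log-likelihood (arviz); the preference
rule is |elpd difference| > 2 paired SE. With two scans per location
the importance weights are often heavy-tailed (Pareto k̂ > 0.7), which
the comparison reports as a warning flag — the strong-vs-null contrast
this package uses LOO for is far larger than the attendant noise.

**Goodness of fit.** Squared Mahalanobis distances of the residuals
against the *specimen-level* predictions, in the metric of the
posterior-mean location-plus-residual covariance, scaled by
(n − p)/(p(n − 1)) and compared to F(p, n − p) quantiles. Residuals
against location-level predictions would be shrunk — each location has
only two scans — and ruin the calibration. The QQ slope is the
quartile-anchored line (tail quantiles are too noisy); under data
simulated from the fitted model it sits slightly below 1 because the
classical constant assumes an estimated covariance.

## 8. Study-level defaults

The model-level generator draws directly from Y = XB + ZU + E at the
study geometry (6 specimens, 2 areas, 5 locations, 2 phases; one pair
removable to give n = 118). Default effects: intercepts at the
log of typical raw values (Sa 0.60 µm, Spc 2.71 µm⁻¹, Sha 123.5 µm²,
Smrk1 19.87 %); zero area effects; erasing effect log(1.02) on Smrk1
and zero elsewhere. Default dispersions (log scale) are chosen so the
implied raw coefficients of variation match the descriptive spread of
such studies — Sa varies ~50 % across locations while Smrk1 varies only
~5 %: specimen SDs (0.35, 0.25, 0.30, 0.03), location SDs (0.45, 0.35,
0.35, 0.03), residual SDs (0.055, 0.055, 0.09, 0.025), diagonal
residual covariance. The surface-level mode generates full before/after
pairs, modulating the target Sa by the specimen/location effects, and
runs the texture computation on them; its induced effects are
approximate where the model-level mode's are exact, so effect-recovery
checks use the model level and directionality checks use the surface
level. All randomness flows from one seed via documented
SeedSequence spawning per specimen/location.

## 9. What passing tests do and do not show

The generator matches the *statistical* structure the analysis assumes:
paired scans with shared location effects, a two-process height
distribution, a wear operator with the observed directional signature,
force pulses at the documented rate, spectra with low-mass markers
present and high-mass markers absent. It does not emulate instrument
artefacts (optical overshoot at edges, anisotropic pixel noise),
real-bone spatial non-stationarity, or the physics of eraser abrasion.
Green tests therefore certify the pipeline's correctness and its
sensitivity at realistic effect sizes — not that any particular bone
will show a 1.02 ratio. Reproducing the original study's printed values
requires its deposited raw scans; pointing the ingestion path
(`read_surface` → preprocessing → `compute_texture_record` →
`SurfaceTextureModel`) at them is the supported route.

## 10. Problem sizes

Default synthetic scans are 160 x 160 at 0.4 µm spacing (64 µm field) —
large enough for ~5 correlation lengths per axis and stable Smrk1
estimates, small enough that a full surface-level study runs in
minutes. Model fits at the full design take tens of seconds per chain
set at the default thinning.
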