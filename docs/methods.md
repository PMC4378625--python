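# Methods

This note documents the models, conventions and numerical choices behind
`phenoshoot`, and what the synthetic benchmarks do and do not establish
about real imaging data.

## Raster and unit conventions

Images use the standard raster convention: origin top-left, y (row)
increasing downward, coordinates 0-based, geometry computed on pixel
centres.  This interacts with the top-view calibration: `Y_ax`, the mean
centre-of-mass row of the two side-view masks, is measured from the top
of the frame, so a taller plant (nearer the overhead camera) has a
*smaller* `Y_ax` and a smaller per-pixel area — consistent with the
positive slope of `K_TV = 9.937e-5·Y_ax + 0.061936`.

Both published calibration constants are treated as **area** factors
(mm² per pixel).  The alternative reading of the side-view constant
0.273 as a linear mm-per-pixel factor is selectable
(`CameraCalibration.linear_side_constant`); under the area reading,
heights use a separate linear factor, default √0.273 ≈ 0.5225 mm/px.
The area reading is the default because it yields plausible pixel
counts for decimetre-scale shoots on a 5-megapixel sensor, which the
linear reading does not.

The classical harvest relative growth rate is implemented as
`R = (ln W₂ − ln W₁)/(t₂ − t₁)`; the denominator is ordered so that a
growing plant has positive R.

## Geometry

Convex hulls use Andrew's monotone chain keeping only extreme points;
cross products on integer pixel coordinates are exact in double
precision, so the vertex set is exact.  The minimum enclosing circle is
the Welzl-type incremental construction run on hull vertices (expected
linear time, exact to ~1e-12 relative, deterministic via an internal
fixed-seed shuffle).  Calliper length is the all-pairs maximum over hull
vertices, which equals the true diameter of the pixel set.

Two conventions coexist deliberately:

* The geometry *operations* (`convex_hull`, `min_enclosing_circle`,
  `calliper_length`) act on pixel centres and are validated against
  exhaustive brute-force oracles (half-plane edge tests, pair/triple
  circle enumeration, all-pairs distances).
* The ratio *traits* (compactness, surface coverage) divide the pixel
  count by hull/circle areas computed over pixel **corners** (the
  centre set Minkowski-padded by the unit square, computed exactly via
  `conv(S⊕Q) = conv(conv(S)⊕Q)`).  With centre-based denominators a
  single-pixel mask would have zero hull area and unbounded
  compactness; the corner convention guarantees
  `0 < coverage ≤ compactness ≤ 1` and the ordering chain
  `fg ≤ hull ≤ circle` on every mask.

Eccentricity is `√(1 − λ₂/λ₁)` from the eigenvalues of the
foreground-coordinate covariance; exactly collinear scatters are
refused (they would give e = 1, outside the trait's [0, 1) domain).

Ligule detection has no published algorithm; the implementation scans
side-view rows from the base upward and reports the lowest row whose
horizontal extent exceeds `width_ratio` (default 2.5) times the stem
width, with the stem width estimated as the 10th percentile of row
extents (stem-only rows are the narrowest).  A leafless silhouette
falls back to ligule = max height.  Both parameters are configurable.

## Segmentation

Nearest-neighbour colour classification uses squared Euclidean distance
in RGB; ties resolve to background, erring toward a smaller plant (the
conservative direction for noise removal).  Cleanup is erosion then
dilation with disc structuring elements (default radius 1 px — the
operator names are published but not the kernel), then removal of
8-connected components below `min_component_px` (default 5), then union
of the survivors into one object.  NIR/RGB registration is assumed
exact for synthetic data; the two-view NIR mean pools pixels over the
union of both side masks (one pooled mean, not a mean of means).

## Colour

The HSI transform is the classical arccos form; hue is undefined (NaN)
for achromatic pixels, which are excluded from means.  Hue means are
circular.  Senescence classifies masked pixels into green [80°, 160°)
and yellow [40°, 80°) hue bands (published categories, unpublished
cut-offs; both configurable) and reports yellow/(green+yellow), pixels
in neither band being excluded.

## Growth models and fitting

Eight models are implemented with these parameterizations: exponential
(M₀, r); power law `(M₀^{1−β} + r t(1−β))^{1/(1−β)}` (β ≠ 1; β → 1 is
the exponential limit; β tunes how RGR declines with size); 3-parameter
logistic `Asym/(1+e^{(t_mid−t)/k})`; 4-parameter logistic with a lower
asymptote; Gompertz `Asym·e^{−b₂ b₃^t}`; Weibull
`Asym − Drop·e^{−e^{lrc} t^{pwr}}`; Richards
`Asym(1+ν e^{(t_mid−t)/k})^{−1/ν}`; and the Yin beta growth function
(M_max, t_e, t_m).  AGR and RGR are analytic for the exponential
(r·M), power law (r·M^β) and 3PL ((M/k)(1−M/Asym)); other models use
central differences with step 1e-4 of the time scale.

Fitting is Gaussian nonlinear least squares: bounded trust-region
(`scipy.optimize.least_squares`, ftol/xtol/gtol 1e-10, iteration budget
400 per parameter) started from self-start heuristics (logistic:
Asym = 1.05·max, t_mid by half-maximum interpolation, k from a
logit-linearization slope; power law: β and r from regressing local
log-RGR on log size; analogous linearizations for the rest).  Pooled
cohorts are collapsed to per-timepoint means for initialization only.
`AIC = n ln(RSS/n) + 2(p+1)`; `R² = 1 − RSS/TSS`, both on the
unweighted scale.

**Convergence is a recorded state, never an exception**, and it means
*statistically valid* convergence, not merely optimizer termination.  A
fit is recorded non-converged when (a) the optimizer fails or exhausts
its budget, (b) the scale-invariant condition number of the
parameter-correlation matrix exceeds 1e10 (the Wald covariance is not
estimable), or (c) an estimate is pinned at a reparameterization-limit
boundary (β → 1, Gompertz b₃ → 1, Richards ν → 0 or its cap) — the
optimizer diverging toward another model family.  Well-posed fits in
the simulated designs have correlation condition numbers 10–1e5, far
from the cutoff.

Residual variance: the default is homoscedastic.  `variance="power"`
derives weights 1/fitted (sd proportional to the mean) by one
reweighting pass — the correct variance model for multiplicative noise,
and the mode used by the statistical-calibration benchmarks, where it
restores ~95% Wald and prediction-band coverage that the homoscedastic
fit understates on multiplicative-noise data.

Population prediction bands draw parameter vectors from
N(estimates, covariance) (nearest-PSD repair with a warning if needed;
draws projected into the parameter domain), evaluate the curve per
draw, and take pointwise quantiles; deterministic given the seed
(default 20110301).

Model selection: candidates failing (in the recorded sense) on any
group are disqualified; survivors are ranked by mean AIC across groups;
near-ties (ΔAIC < 2) go to the model with fewer parameters, then to the
narrower mean prediction-band width.  If every candidate is
disqualified the error lists per-group diagnostics.

The inflection day is t_mid exactly for the logistics and a bounded
scalar search (tolerance 1e-7 d) for the maximum of AGR for the other
sigmoids; non-sigmoidal models raise.

## Synthetic data: what it emulates, and what it does not

Plants are rendered as a stem rectangle plus tapered quadratic-Bézier
leaf ribbons radiating at fixed azimuths (optional smaller tillers),
on a uniform background.  "Rolled" halves ribbon width, realizing leaf
rolling operationally as a known projected-area reduction.  Senescence
paints an exact rounded fraction of foreground pixels yellow, tip-first.
Foreground colours are generated by the inverse HSI transform at the
requested hues, so the spectral ground truth is the quantized base
colours' hue; the seed drives only per-pixel intensity jitter (hue- and
mask-preserving), making the geometric and spectral ground truth
identical across seeds and rendered outputs byte-identical for a fixed
seed.  The NIR ground-truth grey is linear in moisture between the dry
and wet grey levels, with symmetric integer jitter.

Trajectories are model curves times unit-mean lognormal factors
(σ² = ln(1+cv²)), so simulated areas are positive, mean-unbiased and
have exactly the requested CV.  Two canonical designs are bundled:

* **Watering trial** (sigmoidal): 4 variety×treatment groups × 14
  plants, daily imaging days 18–47, logistic3 truth with asymptotes
  650–3100 mm², inflections at days 25.6–37, noise CV 5%.
* **Nutrient trial** (exponential phase): 6 groups × 6 plants, imaging
  3×/week days 14–30, power-law truth (M₀ = 160 mm², r = 0.222,
  β = 0.97), i.e. RGR ≈ 0.17 d⁻¹ declining only slightly with size.

Diurnal pairs multiply a pre-dawn area by (1 − loss) with per-plant
loss ~ N(0.22, 0.01) truncated to [0, 0.9] for water-limited cohorts;
the expected pre-dawn increase is 1/0.78 − 1 ≈ 28.2%.  Watering logs
add transpiration+evaporation to the planted pot and evaporation alone
to an empty control (defaults 45 + 8 g/day for 28 days, ≈1.5 kg).

The generator does **not** emulate: occlusion between overlapping
leaves of neighbouring plants, shadows, specular reflections,
perspective distortion, soil/pot pixels, wind motion blur, or
chlorophyll-dependent hue gradients within a leaf.  Passing the
benchmarks therefore demonstrates that the *computational chain* is
correct and statistically calibrated under its stated assumptions — not
that segmentation of real glasshouse imagery reaches the same
accuracy.  On real data the colour palettes, hue bands and
morphological radii would need tuning, and validation against
destructive harvests (as in the trait-validation regressions) remains
essential.

## Numerical and degenerate-input choices

* Empty masks: flagged and propagated (traits NaN), never fatal, except
  where a mean is mathematically undefined (NIR overlay, mean hue) —
  those raise.
* Empty plant specs render as valid empty results.
* Lenient model evaluation (used inside optimization) clips domains;
  strict evaluation (the public default) raises naming the offending t.
* Power-law fitting restricts β to (−5, 0.999], which keeps the base
  positive for t ≥ 0; `evaluate` supports β > 1 with a domain check.
* Constant series self-start as degenerate with a warning
  (Asym = 1.05·value); monotone-decreasing series are rejected — these
  are growth models.
* Identical diurnal pairs give p = 1 (the paired t statistic is 0/0).
* All simulation sizes in the test benchmarks (200-mask geometry
  suite, 200-replicate recovery, 100 + 30 selection replicates,
  30-plant segmentation sweep) were chosen to give stable Monte-Carlo
  estimates at interactive runtimes on one CPU.
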