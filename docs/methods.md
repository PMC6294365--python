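# Methods

This note documents the models, numerical choices and known limitations of
the `ndvitrend` pipeline, and what its synthetic tests do and do not
demonstrate about real data.

## Data model and conventions

All rasters share one regular grid: 0-based row/col indexing, row 0 at the
northern edge, origin at the upper-left pixel corner, coordinates in planar
meters. Distances are computed from pixel centers on the plane (no geodesic
math); synthetic scenes are defined directly in projected meters, so this is
exact for them. Continuous rasters use NaN as nodata; categorical rasters
carry integer codes with a code → label map. Monthly stacks must have a
strictly consecutive (year, month) axis.

Slope and aspect come from the Horn 3×3 kernel, the de-facto GIS standard;
at grid edges the DEM is extended by odd reflection (linear extrapolation),
which differentiates inclined planes exactly everywhere. Aspect is the
downslope azimuth, degrees clockwise from north, with a distinguished flat
code (−1) where the gradient vanishes.

The polygon partition intersects mean-annual-precipitation (MAP) bands with
catchments. Band edges are half-open, `[lo + k·w, lo + (k+1)·w)` with
width w = 50 mm, anchored at the landscape minimum rounded down to a
multiple of w; only nonempty (band, catchment) combinations receive ids,
numbered 1..n in (band, catchment) order.

## Dynamic factor model

Per-polygon standardized NDVI series are modelled as

    y_t = μ + Γ α_t + D x_t + ε_t,   ε_t ~ N(0, diag(R))
    α_t = α_{t−1} + η_t,             η_t ~ N(0, I_M)

* M random-walk common trends with identity state noise and diagonal
  observation covariance — the canonical identifiable "common trends +
  explanatory variables" form. A full R is not supportable at ~50 series ×
  120 months. Loadings have zeros strictly above the diagonal and a
  non-negative diagonal, imposed structurally in the M-step and by a final
  sign flip.
* Estimation is EM. The E-step runs a Kalman filter in information form
  (the diagonal R makes each measurement update O(N·M²)) and an RTS
  smoother; the log-likelihood comes from the prediction-error decomposition
  through the matrix determinant lemma. The M-step is an exact row-wise GLS
  update, so the likelihood is non-decreasing at every iteration — the code
  asserts this and aborts on violation. The filter/smoother kernel is
  numba-compiled (a pure-NumPy fallback exists).
* Missing observations are skipped in both steps; no imputation.
* Initialization is deterministic: μ and D from per-series OLS, R from OLS
  residual variances, and Γ from a PCA (SVD) of the OLS residual matrix
  projected onto the lower-triangular constraint with a fixed sign
  convention. A flat-constant loading start was found to strand EM in a
  local optimum on near-noise-free factor data; the PCA start begins at the
  dominant shared-variation directions and does not. Seeded jittered
  restarts (`n_starts`) remain available.
* Convergence: |Δ log L| < 1e-6, max 2000 iterations, initial state prior
  N(0, 5·I). Random-walk factor likelihoods are flat near the optimum, so
  the likelihood often crawls below tol only after the parameters have
  stabilized; coefficient estimates are typically stable after a few
  hundred iterations.
* AIC = −2 log L + 2p with p = free loadings (N·M − M(M−1)/2) + N·K
  coefficients + N intercepts + N variances. `select_model` minimizes AIC
  over trend counts / covariate subsets, breaking ties toward fewer
  parameters.
* Predictions are the smoothed fitted values μ + Γα̂ + Dx, back-transformed
  through the stored per-series mean and scale. They are in-sample fitted
  values, not one-step-ahead forecasts.

## Residual trend surfaces

Residuals d(pixel, t) = obs − polygon prediction are tested per pixel with
the seasonal Mann-Kendall statistic: Kendall's S within each calendar month
across years, tie-corrected variances, S and var summed over months
(independent-seasons assumption; no serial-correlation correction — a
`continuity`/config flag level of correction is the only option exposed).
τ is S_total divided by the summed tie-adjusted (tau-b style) maximal pair
counts, so τ ∈ [−1, 1] and τ = ±1 for perfect within-month monotonicity.

**Continuity correction.** The classical ±1 correction to S is *off* by
default. For the 10-year × 12-month design the exact null distribution of
S_total (convolution of twelve Mahonian S distributions for n = 10) puts the
two-sided rejection probability at nominal α = 0.1 at 0.093 with the
correction and 0.104 without it: the corrected test is conservative at this
sample size while the uncorrected one is nearly calibrated. For single
months with very few years the correction is the better approximation (at
n = 5 it tracks the exact permutation p to within 0.02) and can be enabled
via `continuity=True`.

Sen's slope is computed month-wise — the median of within-month pairwise
slopes, in NDVI per year (year indices are the pair spacing), then the
median over months that have at least two observations.

Classification at α = 0.1 (per-pixel, no multiplicity adjustment, matching
standard practice for trend surfaces): p > α → none; otherwise the sign of
τ sets under (positive: observed above prediction) or over. Within each
significant sign group, pixels with |τ| at or above the group median are
promoted to "extreme" — a parameter-free four-way split; a fixed |τ| cutoff
can be supplied instead. Codes: 0 none, ±1 significant, ±2 extreme.

The summary reports class percentages at two decimals plus both the sum of
the under/over totals and the complement of the correct fraction; the two
can differ in the last digit by rounding, so both are printed.

## Random-forest attribution

Sampling draws a fixed number of points per significant class with a
minimum spacing (greedy, seeded, error on shortfall). Features are extracted
at the sampled pixels in a documented fixed order; points on nodata are
rejected with a warning. The headline classifier is binary under vs over —
the four-way labels are retained for the covariate histograms and for
per-class permutation importances.

The forest grows 500 (default) unpruned CART trees on bootstrap samples of
the table (drawn with replacement at full table size, so the expected
unique fraction per tree is 1 − e⁻¹ ≈ 2/3), Gini splits over
mtry = ⌊√p⌋ randomly drawn features, to purity (min leaf 1). Individual
trees are grown by scikit-learn's CART; the bagging, OOB vote matrix,
per-tree in-bag indices, OOB error and both importance metrics are owned by
this package and fully seeded. Categorical covariates are one-hot encoded
internally — equivalent to one-vs-rest single-category splits — and
importances are summed back to the parent covariate. Majority votes break
ties toward the smaller class code.

Mean decrease in accuracy permutes a covariate's values across *all* of a
tree's OOB rows and measures the accuracy drop (averaged over trees);
per-class variants score only rows of one true class while still permuting
across all rows, since permuting within a class would leave a
class-separating feature intact. Gini importance totals the impurity
decrease attributed to a covariate over all splits and trees.

`combined_explained(correct, oob_accuracy)` =
correct + oob_accuracy·(100 − correct)/100 (percent, two decimals):
the fraction of the landscape either directly reproduced by the factor
model or attributed by the forest. OOB accuracy is used as the "accurately
explained" rate of the significant surfaces, it being the only unbiased
computable operationalization.

## Synthetic scenes

`ndvitrend.scene` generates a seeded landscape whose defaults are the study
conditions the pipeline targets: 60×60 cells of 250 m, 10 years of monthly
data, MAP falling linearly north → south across 1400 → 400 mm/yr (with
smoothed noise), three catchments with wavy boundaries, a DEM high in the
north, categorical land cover/soil/country fields, one protected-area
polygon, two roads, four settlements, one river, and population clustered
around settlements. Monthly drivers: precipitation as a MAP-scaled seasonal
profile peaking December–February with zero-inflated shoulder months and
lognormal interannual multipliers (CV 0.25); sinusoidal temperatures with an
elevation lapse; soil moisture as AR(1)-filtered precipitation (memory 0.6);
PET anti-phase with soil moisture; fire as Poisson counts concentrated in
the late dry season and drier (southern) pixels.

Polygon NDVI is built from the generative factor form: an intercept rising
with polygon MAP (0.20–0.55), standardized polygon-mean drivers times the
configured coefficients (defaults, NDVI per driver sd: precipitation 0.05,
soil moisture 0.08, max temperature −0.02, PET −0.03, fire −0.01, mean
temperature 0.01), plus two random-walk common trends with small loadings
(sd 0.008). Pixels add a planted linear drift m·t and Gaussian noise
(sd 0.05), clamped to [−1, 1] with a warning if clamping exceeds 5 %.
Planted drifts (NDVI/yr): +0.010 inside the protected area, −0.010 within
90 m of roads, 1 km of settlements or the top population decile, +0.004 in
the lowest DEM decile. A linear plant keeps ground truth analytically known
for the monotone-trend stage. Distinct seeded substreams drive landscape
geometry, drivers, trends and noise, so changing the noise level does not
move the geometry.

**What the synthetic tests do not show.** The generator has no phenology or
radiative-transfer realism, no spatially correlated noise, no cloud gaps,
no inundation dynamics (only a static mask), and its planted divergences
are exactly linear. Passing tests demonstrate that the pipeline recovers
known structure under its own model assumptions — not that those
assumptions hold for any particular satellite product. Relative humidity
and minimum temperature are not generated; the driver roster is the five
biophysical families above (with mean and max temperature both emitted).

**Minimum detectable effect (pilot).** The polygon-mean component of a
planted drift shifts the polygon's own NDVI series and is absorbed into the
polygon-level prediction — structurally invisible to a residual trend test.
What the trend stage detects is the *within-polygon effective slope*,
m − polygon-mean(m). The committed pilot (`scripts/pilot_sensitivity.py`,
seeds 1–3, default noise) measured correct-sign detection of ≥ 98.6 % for
effective slopes ≥ 0.005 NDVI/yr, against a plateau of 0.88–0.98 for raw
slopes however large; `MIN_DETECTABLE_EFFECT = 0.005` is fixed from that
pilot.

## Pipeline, sizes and degenerate inputs

The CLI stages exchange on-disk artifacts (TIFF + JSON metadata, GeoJSON,
CSV) stamped with the master seed and a config hash, so reports are
re-derivable and byte-identical under identical config + seed. Defaults:
α = 0.1, 500 trees, 50-mm bands, 90 m / 1 km buffers, two common trends.
The sampling plan defaults to 150 points per class at 1.5-cell spacing —
sized to the default 60×60 scene, where each significant class offers a few
hundred eligible pixels; real-landscape runs should scale `rf.n_points` up
(the classical choice is ~1000 per class).

Degenerate inputs fail loudly: constant series cannot be standardized (the
offending polygon is named), n_trends ≥ n_series is rejected as
unidentifiable, a non-positive MAP raster is rejected, empty feature sets
cannot be buffered, classes with too few eligible pixels abort sampling
with the shortfall, and a decreasing EM likelihood raises rather than
returning a bogus fit. Observation variances are floored at 1e-8 so
noise-free series remain filterable.

## Known limitations

* The DFA absorbs polygon-mean divergences (see the pilot note); the method
  attributes only within-polygon heterogeneity.
* No spatial false-discovery control across pixels; α = 0.1 is per pixel.
* No serial-correlation correction between seasons in the trend test.
* The forest's OOB accuracy on sampled points is treated as the attribution
  rate for the whole significant surface; spatial autocorrelation between
  sample points can make it optimistic on real data (minimum spacing
  mitigates, does not remove, this).
* Distances are planar; reprojection of geographic data is out of scope.
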