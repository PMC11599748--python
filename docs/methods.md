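# Methods

## The model

Soil organic carbon density is modelled volumetrically:
OCD(x, y, d) in g C cm⁻³, where (x, y) are WGS84 lon/lat and d is the
depth (cm) at the centre of a sampled soil layer. A single random-forest
regression is fitted with depth as an ordinary predictor next to the
landscape covariates, so the one fitted ensemble predicts at any standard
depth. This "3-D" formulation avoids assuming a parametric depth function
(marsh OCD profiles are often close to depth-stable: concentration falls
while bulk density rises) and lets sparse deep samples borrow strength
from the whole profile.

Layer stocks are obtained by trapezoidal integration of the boundary
predictions:

    stock(0–30)   = (OCD₀ + OCD₃₀) / 2 · 30 · 100   Mg C ha⁻¹
    stock(30–100) = (OCD₃₀ + OCD₁₀₀) / 2 · 70 · 100 Mg C ha⁻¹

The ×100 factor is exact unit conversion (1 g C cm⁻² = 100 Mg C ha⁻¹), not
a tunable. Predictions are clipped at 0 g C cm⁻³ — a documented post-hoc
physical constraint.

### Hyperparameters

| parameter | default | meaning |
|---|---|---|
| `mtry` | 3 | predictors tried per split |
| `min_node` | 5 | minimum terminal-node size |
| `n_trees` | 300 | ensemble size |
| `importance_mode` | impurity | variance-reduction importance |

The tuning grid (mtry 1–5 × min_node {1,2,3,5,10} × trees {100…500})
is available through `model.tune`; on smooth data the CV RMSE varies
little across it, which is why the defaults above are pinned rather than
re-tuned per run. Categorical covariates are one-hot expanded inside the
model; the expansion map is stored on the fitted object so the
dissimilarity index operates in the identical space.

## Spatial cross-validation (k-NNDM)

Training cores cluster heavily in a few regions. Random CV then measures
only within-cluster interpolation, which overstates map skill. k-NNDM CV
builds k = 5 location-level folds whose between-fold nearest-neighbour
(NN) distance distribution matches the distribution of NN distances from
prediction locations (a random sample of marsh pixels, 5000 by default) to
training locations.

Implementation: candidate partitions come from complete-linkage
hierarchical clustering of the training locations (great-circle distance,
haversine, R = 6371 km), cut at every q from k up to a ladder cap, each
cut merged greedily (largest cluster first into the currently smallest
fold) down to k folds. The partition minimizing the Wasserstein-1 distance
between the two NN-distance ECDFs wins; ties go to fewer clusters. The
achieved mismatch is stored as the assignment's `quality`, so the claim
"matched better than random folds" is checkable per run. Folds are
assigned per unique location, never per sample, so depth profiles can
never straddle a fold boundary (leakage guard).

CV metrics: R² = 1 − SSE/SST and RMSE over all held-out pairs pooled
across folds.

## Dissimilarity index, AOA and expected error

The DI of a query point is its minimum distance to the training data in a
predictor space that is centred/scaled with training statistics and
weighted by normalized impurity importance, divided by the mean pairwise
distance among all training points. Training points get a CV-aware DI: the
NN search excludes points of their own fold. Prediction pixels use all
training points. Zero-variance dimensions get weight 0 and are flagged.

AOA threshold = Q75 + 1.5·IQR of the cross-validated training DIs, with
linear-interpolation (type-7) quantiles — the threshold value depends on
the quantile convention, so it is pinned. A pixel at exactly the threshold
is inside. Per layer, the inside indicator is evaluated at the top and
bottom depths and averaged; only an average of 1 (inside at both) counts
as inside — 0.5 is outside.

Expected error: CV residuals are sorted by DI; a sliding window of
max(20, 10 % of samples) yields local RMSEs at the window-median DI; an
isotonic regression (monotone non-decreasing, flat extrapolation beyond
the fitted range) maps DI → expected OCD-level RMSE. Isotonic regression
realizes the same shape constraint as a shape-constrained additive model
with a monotonicity penalty, without extra dependencies, and its step
function is easy to test pointwise. The error is propagated to stock units
with the identical trapezoid used for stocks, so error maps share the
prediction maps' units (Mg C ha⁻¹). The window size is a config knob
(`window_fraction`, `min_window`); the calibration is insensitive to it on
homoscedastic residuals and recovers DI-proportional noise with rank
correlation > 0.9 in the tests.

## Aggregation

Pixel area (ha) = (111.32 km · res) · (111.32 km · res · cos lat) · 100,
evaluated at the pixel centre — the single area convention used
everywhere. Cell (2° by default) and region summaries are area-weighted
over each layer's own inside-AOA pixel set; because the deeper layer's AOA
is systematically smaller, the 0–100 cm per-hectare mean is reported both
as the sum of the per-layer means and on the intersection of the two AOA
sets. Totals are in Tg C (Pg = Tg/1000) and are conservative by
construction: each pixel belongs to exactly one cell and at most one
region, so cell totals and region totals (plus "unassigned") partition the
global total exactly. The bivariate product classifies cells into
low/high prediction × low/high error at the cell medians (echoed in the
output metadata), computed on pre-mask values.

## Synthetic landscapes

The generator emulates the statistical features of the real training data
that drive the method's behaviour:

- covariates: white noise smoothed with a Gaussian kernel (correlation
  length in degrees), standardized over a spatially coherent marsh mask;
  categorical fields are quantile-binned smoothed fields;
- truth: OCD = intercept + Σ effectⱼ·covariateⱼ + depth_effect·d, clipped
  at 0 — linear-additive so that recovery and AOA behaviour are
  predictable while still exercising a nonlinear learner;
- sampling: ~85 % of locations drawn from 3 Gaussian clusters (the
  three-country concentration of the real data), the rest uniform;
  depth-stratified samples with deep (>30 cm) retention ≈ 0.5 by default,
  reproducing the roughly one-third deep-sample share; observation noise
  N(0, noise_sd) with default 0.004 g C cm⁻³ — the noise structure of real
  OCD measurements is not documented, so this is a simulation knob chosen
  to give a realistic signal-to-noise ratio against covariate effects of
  0.003–0.008 g C cm⁻³ per sd, not an estimate;
- cluster labels double as country/realm stand-ins for aggregation.

What the generator does **not** emulate: real covariate marginals and
cross-correlations (tidal amplitude, suspended matter, climate), coastal
geometry, measurement-protocol heterogeneity between source datasets, and
non-additive covariate interactions. Passing tests therefore demonstrate
that the machinery is correct and behaves as designed under realistic
clustering and depth-sparsity — not that real-world accuracy equals the
synthetic one.

## Numerical choices and degenerate inputs

- Nearest-pixel covariate lookup (no interpolation), matching per-pixel
  prediction semantics; cores on nodata pixels are dropped with a logged
  count; rows with missing covariates are dropped, never imputed.
- Grid registration: pixel-centre, row-major from the north-west corner.
- DI denominator uses *all* training points even when fold exclusion
  applies to the numerator; DI is invariant to per-dimension rescaling by
  construction.
- Constant columns: correlation screen reports "undefined" rather than
  propagating NaN; zero-variance predictor dimensions get DI weight 0.
- Ties in tuning go to fewer trees, then larger minimum node size.
- Chunked pixel prediction is bitwise independent of the chunk size.
- All randomness flows from one top-level seed through named per-stage
  substreams, so resumed runs reproduce full runs bit-for-bit.

## Problem sizes

Default synthetic scenes run on 50–64-pixel-square grids (0.02–0.025°)
with 80–400 core locations — sizes chosen so a full pipeline run completes
in seconds on a laptop while still containing distinct geographic
clusters, out-of-envelope area for the AOA, and thousands of depth
samples. Resolution enters no formula except pixel area, so behaviour at
30 m native resolution differs only in scale.

## Known limitations

- The AOA is a coverage diagnostic, not a prediction interval; no
  conformal or quantile-forest uncertainty is provided.
- No depth profiles beyond 1 m; shallow-soil truncation (marshes whose
  organic layer is thinner than 30 cm) is not modelled.
- Region summaries rely on user-supplied labels; no real
  realm/country geometries are bundled.
- The k-NNDM search is a reproducible variant pinned to the stated
  matching objective (ECDF Wasserstein-1 over a clustering ladder); other
  implementations may find different folds with similar quality.
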