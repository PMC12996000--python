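# Methods

`aquaretrieve` implements an empirical retrieval chain for optically complex
(Case-2) inland waters: mask the water surface, derive spectral features,
pair them with in-situ samples, fit a regression model, and map the fitted
relation across the scene. This note documents the models, the defaults and
the reasoning behind the open design choices.

## Scope and assumptions

The engine consumes **surface reflectance**. Atmospheric correction is
delegated to an external ACOLITE run (the package only generates its
settings files); any surface-reflectance GeoTIFF product works. Reflectance
outside [−0.05, 1.5] is treated as nodata — small negative values are a
normal atmospheric-correction residual over dark water, but anything beyond
that tolerance is physically implausible.

Coordinate handling is deliberately minimal: all rasters of a scene must
share one CRS and origin, and station tables must already be expressed in
that CRS (projected x/y). Reprojection is out of scope; pixel indices are
0-based row-major, a pixel's georeferenced position is its center, and
windows are half-open.

## Water masking

Water evidence comes from the McFeeters NDWI, (green − nir)/(green + nir),
which is strongly positive over open water and negative over vegetated land.
The scene-adaptive cutoff is estimated by fitting a two-component Gaussian
mixture to the NDWI sample (EM, seeded, three restarts) and solving for the
crossing of the weighted component densities between the two means by
bisection (tolerance 1e-6 in index units). For equal weights and variances
this reduces to the midpoint of the means. A fit whose minor component
weight falls below 0.02 is flagged "no bimodal structure"; a threshold is
still returned so headless runs do not stall, but the warning is surfaced.

Quality screening uses the providers' own layers: Sentinel-2 SCL classes
{0, 1, 3, 8, 9, 10} (no-data, defective, cloud shadow, medium/high cloud,
cirrus) and Landsat Collection-2 QA_PIXEL bits {0–4} (fill, dilated cloud,
cirrus, cloud, cloud shadow) are invalid by default. Cloud shadows matter
disproportionately here because water retrieval is a dark-target problem.
Both code tables are editable config, since product dialects drift between
collection versions.

The final validity rule is fixed: *valid = water evidence AND quality*,
i.e. quality masks always intersect; union is available for combining
alternative water-evidence masks. Shoreline mixing is handled by morphological
erosion with an 8-connected 3×3 element (a pixel survives erosion by *k*
iff its Chebyshev ball of radius *k* is entirely true); buffer distances in
meters are converted to pixels by rounding up. Vector boundaries are
buffered in shapely (negative shrinks) and rasterized by the
pixel-center-in-polygon rule.

## Spectral features

Features are declarative: name, kind (band / ratio / difference /
normalized difference) and operand roles. Built-ins are NDCI
(rededge − red)/(rededge + red), NDTI (red − green)/(red + green), the
blue/green ratio (BGR, a CDOM proxy), red/nir, green/blue and red/blue
ratios, and the raw bands. Ratio direction follows the index's conventional
name (first-named band is the numerator). Non-positive denominators yield
nodata rather than clipped values: silently clipping reflectance ratios
biases downstream regressions.

## Matchups

Each station maps to its containing pixel; every feature is summarised over
a centered window using a robust statistic across mask-true pixels. Defaults:
3×3 window, median, and a minimum valid-pixel fraction of 0.5 — below that
the row is flagged `low_valid_fraction` and excluded from fitting (still
written to the table, so the exclusion is auditable). Windows clipped at the
scene edge are flagged; stations outside the scene carry nodata predictors.
Timestamps are carried through for provenance but not matched temporally:
the engine is a single-scene tool and assumes the campaign was designed to
be synchronous with the overpass.

## Regression models and the partitioned ensemble

Global candidates are linear regression, random forest (default 200 trees,
min leaf 3, seeded) and RBF support-vector regression (C = 10, ε = 0.1,
inputs standardized with train-set mean/sd stored in the model). All fits go
through scikit-learn.

The spectral-space partitioned ensemble (SPE) addresses the heteroscedastic
residuals that a single global model produces across optical water types:

1. A standard variance-reducing regression tree on the chosen partition
   features (default: all features) versus the response defines the
   partition, grown to `max_depth` with at least `min_leaf_n` rows per leaf.
   Routing descends with the convention *left iff feature ≤ split*.
2. Within each leaf, every candidate is scored by cross-validated RMSE on
   that leaf's rows; the best candidate is refit on all leaf rows. Ties
   break by candidate list order, so with LR listed first the simplest
   model wins.
3. A global fallback — the best candidate by whole-table CV — serves leaves
   that cannot support a validated submodel and any vector with a missing
   split feature.

Defaults are `max_depth` 2 and `min_leaf_n` 15: field campaigns in this
domain typically provide a few dozen samples, which cannot support deep
partitions. `max_depth` 0 degenerates exactly (bit-identically) to the best
global candidate.

Because the split points minimise the SSE of constant leaf fits, they do
not land exactly on a kink of a continuous piecewise-linear relation; the
partition instead brackets the kink and the leaf containing it absorbs the
residual error. This is intentional — the partition criterion is kept
standard rather than co-optimised with the leaf models.

Validation is honest leave-one-out: each fold refits the *entire* procedure,
including the partition, on the remaining rows. A fold that cannot fit
contributes a plain least-squares fallback prediction and is counted in the
report. Leaf-candidate *selection* inside each fold may use 5-fold CV
instead of LOOCV (`selection_cv`); the pipeline defaults to 5-fold there
because nested LOOCV-in-LOOCV with forest candidates is quadratically
expensive while changing selections only rarely. Metrics are
R² = 1 − SSE/SS_tot (undefined for zero-variance observations), RMSE and
MAE in response units.

## Mapping and trophic state

Prediction is applied block-wise (default 512×512 windows) so full scenes
run in bounded memory; features are recomputed per block for mask-true
pixels only. Since every feature is pixel-local, the output is bit-identical
across block sizes and worker counts. Negative predictions are clipped to 0
and counted in the raster's clip report — concentrations are non-negative,
and the count makes extrapolation problems visible rather than silent.

Chlorophyll maps convert to Carlson's trophic state index,
TSI = 9.81·ln(chl) + 30.6 with chl in µg/L (≡ mg m⁻³); non-positive or
nodata chlorophyll propagates as nodata. Classification uses left-open bins
with default boundaries (40, 50, 70) separating oligo-, meso-, eu- and
hypereutrophic classes; a TSI exactly on a boundary goes to the lower bin.
Boundaries are a config item since operational products often use
site-specific thresholds.

## Raster I/O

GeoTIFFs are written through `tifffile` with the standard
ModelPixelScale/ModelTiepoint tags, the GDAL nodata tag, and a JSON metadata
block (transform, CRS label, units, band names, provenance) in the image
description, so files round-trip exactly and remain readable by common GIS
software. Nodata is NaN in memory and −9999 on disk (255 for uint8 masks
and class rasters). Resampling to a common grid uses bilinear interpolation
for reflectance and nearest-neighbour for categorical quality layers, so
class codes are never mixed; the common grid is the finest declared
resolution.

## Synthetic scenes

The generator emulates a single-campaign lake or river study: a land /
water / cloud class map, per-class reflectance spectra with i.i.d. Gaussian
noise (default sd 0.001, a realistic post-correction noise floor), SCL and
QA_PIXEL layers encoded consistently with the masking conventions, and
stations sampled uniformly over interior water (≥ 2 px from shore).

Class spectra are chosen so NDWI is strongly bimodal (water green ≫ nir,
land nir ≫ green). Over water, a chlorophyll "driver" field raises the
red-edge band by up to 0.03, so NDCI increases monotonically with simulated
chlorophyll. The disk lake uses a quadratic radial bloom profile —
concentrated in the center with smooth falloff — which makes the driver
area-uniform on [0, 1], spreading station responses over the full response
range. The default truth relation is piecewise linear in NDCI spanning
roughly 1–75 µg/L, matching the magnitude of a eutrophic reservoir bloom;
the default campaign size is 56 stations with observation noise at 5 % of
the realised response range. All randomness derives from one recipe seed
through named substreams (geometry, noise, stations).

What the generator does **not** emulate: adjacency effects, sun glint,
spatially correlated atmospheric residuals, sensor striping, mixed shoreline
pixels with intermediate spectra, or temporal mismatch between overpass and
sampling. Tests passing on synthetic scenes therefore demonstrate the
correctness of the processing chain and the statistical machinery, not
field-accuracy of retrievals on real imagery — real deployments still
require a local calibration campaign.

## Problem sizes used in the built-in checks

The verification suite and the reproduction script use 256×256 scenes
(700×500 for the block-invariance check) with 56-station campaigns, 200-row
piecewise calibration samples, and 20-seed averages for all stochastic
summaries. These sizes keep every quantity estimable with stable means
while the whole suite runs in a few minutes on one CPU.

## Known limitations

- No reprojection: stations and boundaries must come in the scene CRS.
- Single-scene workflow: no multi-temporal matchup windows or compositing.
- The SPE requires at least 2·`min_leaf_n` usable rows; below that it
  refuses to partition rather than silently degrading.
- GMM thresholding assumes a two-mode NDWI histogram; scenes that are
  nearly all water or all land trigger the unimodality warning and should
  use a fixed cutoff instead.
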