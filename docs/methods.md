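# Methods

This note documents the models, parameter choices and numerical
conventions behind the package, and what the synthetic-data tests do and
do not demonstrate about real satellite data.

## Satellite quantification chain

**AFAI.** The index is computed per pixel as
`Rrc(748) − [Rrc(667) + (Rrc(869) − Rrc(667)) × 81/202]`. Two properties
drive everything downstream: the index is invariant to a flat spectral
offset (the linear baseline absorbs it) and is linear in Rrc(748) with unit
slope. Missing reflectance (NaN) in any of the three bands propagates to a
NaN index, never to 0.

**8-bit scalings.** The distribution products quantise AFAI linearly over
[−0.001, 0.003] and Rrc logarithmically over [0.0075, 0.2]. Inputs outside
the range are clipped and ties round half-up; the product ranges are fixed
but the rounding convention is ours (the round-trip error is at most half a
quantisation step, 0.004/255/2 for AFAI). Quantisation is provided for
product compatibility; the pipeline itself runs in float.

**Valid mask.** A pixel is excluded when flagged land or cloud/ice, or when
its centre lies within 10 km of a land-flagged pixel centre or 2 km of a
cloud-flagged pixel centre. Distance is Euclidean between pixel centres on
the projected grid (computed with an exact Euclidean distance transform),
not geodesic: on a 1-km cylindrical-equidistant product at the latitudes of
interest the difference is far below one pixel. Whether the operational
product measures buffers centre-to-centre or edge-to-edge is not documented;
centre-to-centre is used. The two buffers are independent and union-ed, and
per-pixel provenance (land / near-land / cloud / near-cloud) is retained.

**Detection.** Detection quality is explicitly not the package's
contribution — the operational product uses a trained segmentation network.
Detection is therefore a pluggable interface
`(afai_values, valid_mask) -> bool array`. The default detector retains the
256×256 tiling of the operational analysis as its background-statistics
window: a valid pixel is flagged when its AFAI exceeds the tile's valid-pixel
median by more than a threshold (default 10⁻⁴ for noiseless work, 5×10⁻⁴
≈ 4σ of the propagated index noise at band noise 10⁻⁴). Thresholds must be
positive; detections never occur on invalid pixels regardless of the
detector.

**Patches and ΔAFAI.** Detected pixels are grouped 8-connected ("contiguous"
is not further specified; 8-connectivity is the permissive reading) and
components under 3 pixels are dropped and counted in a log record. The
"13-pixel dilation" that defines the background sample is implemented as
morphological dilation by a square structuring element of Chebyshev radius
13 (a 27×27 neighbourhood); the radius is configurable since the element is
not documented. The background is the median AFAI over pixels in the
dilation footprint that are valid and not detected anywhere in the scene;
one median per patch (a per-pixel windowed variant is available behind a
flag, since the product description is ambiguous between the two). Patches
with an empty background sample are flagged and excluded from
quantification rather than given a fabricated background.

**Unmixing.** `f = clamp(ΔAFAI / 4.41×10⁻², 0, 1)`. Negative ΔAFAI maps to
coverage 0 (the pixel is retained and contributes zero biomass); values
above the full-coverage constant clip to 1. This keeps the estimator
bounded, as the linear scaling implies.

**Composites and biomass.** 0.5° cells are half-open
[lon, lon+0.5) × [lat, lat+0.5) anchored at half-integer degrees; pixel
membership is by centre. A cell's value is the arithmetic mean fractional
coverage over every valid pixel observation in the period — non-detected
valid pixels count as 0, masked pixels are excluded from numerator and
denominator — so the composite is per-area mean coverage. Never-observed
cells are explicit missing records (the composite grid spans the bounding
box of observed cells). Biomass is mean coverage × spherical cell area
(mean Earth radius 6371 km) × 3.34 kg m⁻², in metric tons; "million tons"
means metric tons wet weight throughout. Region geometries ship as editable
polygon configs; the analysis-region outlines published for the Sargasso
Sea study are approximate, so all tests use synthetic rectangles and no
default geometry is load-bearing.

**Calendar.** Ecological years run March–February (January/February belong
to the previous year, matching the March bloom onset); seasons are MAM,
JJA, SON, DJF, with winter carrying the ecological year of its December.
Anomalous calendar years can be excluded from series for mapping purposes;
period statistics include them by default.

## Synthetic scenes

The generator is the exact forward model of the inverse problem the
pipeline solves. The background is a flat per-band clear-water Rrc
spectrum; each injected raft pixel with coverage `f` raises **only** the
748-nm band by `f × 4.41×10⁻²`. Because AFAI is linear in Rrc(748) with
unit slope, the noiseless index excess is exactly `f × 4.41×10⁻²` and the
unmixing returns `f` to floating-point precision. This makes truth-recovery
tests sharp, but it is a testability device, not radiative-transfer
realism: real sub-pixel mixing perturbs several bands, the background is
not flat, and detection against a learned model behaves differently. A
passing recovery test therefore validates the quantification algebra and
bookkeeping, not MODIS-scene performance.

Grid conventions: the native pixel step is 1/112° (~992.8 m on the mean
sphere) — the nominal "1-km" resolution of a degree-defined
cylindrical-equidistant product — so a 0.5° composite cell holds exactly
56×56 pixels. With a metric 1000-m step, cells would alternate between 55²
and 56² member pixels while keeping the same spherical area, injecting a
systematic ~0.5–1% bias into "mean coverage × cell area" biomass; the
angular step models how such products are actually gridded and leaves only
the spherical-vs-planar term (<0.01% near the equator). Default scene
origins sit on 0.5° grid lines near the equator so scene edges coincide
with cell edges; a cell only partially covered by observations otherwise
extrapolates its mean to the full cell area. Pixel size, origin and date
are all configurable.

Land is a configurable border strip and clouds are random filled discs —
the simplest geometries that exercise both buffer rules. By default random
cloud blobs are rejected within 16 pixels of injected rafts
(`cloud_keepout_px`) so configured truth stays quantifiable; set it to 0 to
study censoring by masks. Band noise is independent zero-mean Gaussian per
pixel and band, truncated at zero reflectance. Truth biomass is
`Σ f × pixel area × 3.34 kg m⁻²`.

## Synthetic tows

Tows are placed uniformly in a region's bounding box with nominal distance
speed × duration (2 kn × 30 min = 1852 m = 1.0 nm; 1 kn = 1852 m h⁻¹),
optional duration jitter, and timestamps drawn within the configured
season. Per-tow total mass is log-normal with arithmetic mean equal to
regional density × swept area and coefficient of variation
`patchiness_cv` (default 1.0 — *Sargassum* is strongly aggregated into
windrows and the field data are highly skewed; no distributional form is
documented, so the log-normal is a modelling choice), optionally
zero-inflated by an encounter probability. Mass is split across the three
morphotypes deterministically by the configured mix. The ratio-of-sums
weighted mean is unbiased for the configured density under this model,
which the Monte-Carlo recovery test exploits.

In-situ conventions: GPS-derived distances use the haversine formula on a
6371-km sphere; minute-by-minute tracks sum consecutive great-circle legs.
Swept width is the 1.0-m net mouth. Per-morphotype weighted densities use
the full group's swept area as denominator (so they add exactly to the
total); groups with zero tows are reported as explicit no-data records,
distinct from zero density. Tows falling outside all configured regions are
grouped under `unclassified` rather than dropped silently.

## Statistics

The variance-ratio F-test puts the larger sample variance in the numerator
(F ≥ 1) and doubles the upper-tail probability for a two-sided p (capped at
1). The auto-flavour t-test applies the conventional two-stage rule: pooled
variance when the F-test accepts equality at α = 0.05, Welch otherwise.
The operational description of this rule is ambiguous about which branch
drops the homoscedasticity assumption; both flavours are callable directly
so either convention is reproducible. Under the null with normal samples
(n = 15 vs 9) the two-stage procedure's type-I rate is calibrated at ~5%,
which the acceptance suite verifies by simulation.

Box statistics use type-7 (linear-interpolation) quartiles — the common
plotting default; no method is documented for the source figures — with
whiskers at the most extreme data points within 1.5 × IQR of the quartiles
and everything beyond flagged as an outlier. Note the whiskers are data
points and can fall inside the interpolated quartiles for heavily tied
samples.

## Problem sizes and numerical notes

Truth-recovery runs use 256×256 scenes with 20 3×3 rafts spanning coverages
0.05–1.0, noiseless and at band noise σ = 10⁻⁴ (20 replicates); oracle
equivalence uses randomized grids ≤64×64 against brute-force all-pairs /
BFS / enumeration references and 1,000 randomized sample pairs for the
scalar statistics at 10⁻¹⁰; the type-I calibration uses 10,000 simulated
pairs. These sizes make the full suite run in about a minute while keeping
every rule path exercised. Missing data are NaN throughout raster
operations; quantisation rounds half-up; medians over even-sized samples
interpolate (numpy convention).

## Known limitations

- Single-band signal injection and flat backgrounds make synthetic recovery
  easier than real-scene retrieval; detector skill on real imagery is out
  of scope.
- The default threshold detector is deliberately simple; it will miss dim
  rafts near the noise floor and is only intended as a stand-in behind the
  detector interface.
- Region polygons are user-supplied; no authoritative boundaries are
  bundled.
- Morphotype composition is in-situ only; no spectral discrimination is
  attempted.
- Composites assume the per-cell mean of observed pixels extrapolates to
  the whole cell; heavily masked cells therefore carry higher variance and
  partial-coverage bias in real data.
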