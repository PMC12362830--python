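# Methods

## Data model

An MSI scan is a set of pixels on an integer (col, row) grid, each
with a centroided spectrum (ascending m/z, non-negative intensities)
and a physical pixel size (default 50 µm).  The on-disk format is a
plain-text pixel table — one `x y mz intensity` record per line,
whitespace- or comma-delimited with an optional single header line,
delimiter auto-detected.  Duplicate (x, y, m/z) records are summed
(centroided exports sometimes split a peak); zero-intensity records
are dropped on load.  A pixel whose spectrum is entirely empty cannot
be represented in this format: writing emits no rows for it, so it is
absent after a round trip.  Input intensities are taken as given; no
TIC or lock-mass correction is applied or assumed.

An ion image sums, per pixel, the intensities of peaks within a
tolerance window of a target m/z.  The default window is ±0.02 Da:
channels are quoted to three decimals on QTof-class instruments, so
the window must absorb rounding while excluding neighbouring peaks; a
ppm mode is available.  Exact masses for channel definitions use
IUPAC monoisotopic atomic masses with the electron mass subtracted per
positive charge; protonated species add one hydrogen per charge.
Choline [C5H14NO]⁺ evaluates to 104.107 and protonated terbinafine
[C21H25N + H]⁺ to 292.206.

## Tissue segmentation

Pixels are clustered with scikit-learn k-means (k-means++
initialisation, 10 restarts, 300 iteration cap, tolerance 1e-4, fixed
seed, default k = 15) on binned spectral features: peak intensities
histogrammed at 1 Da over the acquired m/z range, each pixel vector
divided by its sum.  Per-pixel-sum normalization makes clusters
reflect spectral composition rather than overall abundance; the m/z
range and bin width are configurable because the most informative
sub-range is specimen-dependent.

Tissue clusters are then selected either manually (explicit label
list — the scriptable equivalent of interactive inspection) or
automatically: clusters are ranked by mean intensity in an endogenous
marker channel (choline by default) and every cluster above 0.25 of
the top cluster's mean is kept.  The 0.25 threshold is a named,
overridable constant; it sits well below the tissue plateau and well
above background leakage on every synthetic condition we generate,
but real specimens with weak marker signal should use manual mode.
Finally, detached specks are removed by keeping the largest
8-connected component, optionally after an inclusive crop box.

## Straightening and depth layers

With the stratum corneum (SC) side given by the user (no automatic
orientation detection — sections are arranged manually at scan time),
coordinates are rotated so depth increases along rows.  The depth
ordinate is then transformed linearly:

    Y' = (Y − Avg(Y)) / Var(Y),  then  Y' = Y' · 100000

Two centring modes are provided because a single global affine map
cannot remove curvature: the default *per-column* mode takes Avg(Y)
within each across-band column (flattening the band's midline to
zero), then divides by the variance of the centred ordinate over all
tissue pixels; the *global* mode applies the formula verbatim.
Division by the variance rather than the standard deviation is the
primary behaviour, dimensionally odd as it is, because that is the
transform this tool standardises on; a `use_std` switch exposes the
conventional scaling.  Both the variance divisor and the ×100000
factor are affine rescalings, so they never change layer membership —
asserted by test.  Zero variance (single-row tissue) raises a
degenerate-geometry error.

Layer assignment partitions Y' into n layers, index 0 at the SC.
Internally Y' is mapped to unit range and rounded to 12 decimals so
membership is bit-stable under affine rescaling (exact bin-edge ties
break upward consistently).  Two methods:

- `kmeans-1d`: scikit-learn KMeans with k = n_layers, initialised at
  equal-mass quantile centres.  On one-dimensional data k-means++
  restarts routinely converge to uneven local optima; quantile
  initialisation starts at the balanced interval solution and stays
  there, which also makes the method agree exactly with equal-width
  binning on rectangular tissue.  If quantile centres tie (heavily
  skewed Y'), it falls back to seeded k-means++.  Clusters are
  relabelled by ascending centre.
- `equal-width-bins`: [min Y', max Y'] split into n equal intervals.

The per-layer width in µm is the mean pixel count of the layer along
the depth axis (per across-band column) times the pixel size; a
50-row rectangle split into 50 layers yields one row per layer, 50 µm
each.  Layers are reprojected onto the original grid as an integer
raster with −1 for background.

## Permeation profiles

The per-layer statistic is the arithmetic mean of the drug-channel
ion image over *all* pixels of the layer, zeros included — "average
signal in the layer" read literally, and the only reading independent
of the detection threshold.  Fractions are means normalized by their
sum (Σ = 1 within 1e-9 whenever total signal > 0; a blank section is
flagged `valid = False` with zero fractions rather than NaNs).  Depth
midpoints accumulate the per-layer mean widths, so irregular layers
report honest depths.  The manual-ROI mode applies the same
mean-and-normalize contract to hand-defined masks of stated width
(default one pixel = 50 µm) and reproduces the automatic profile
exactly when fed the reprojected automatic layers.

`depth_of_detection` returns the deeper bound of the deepest layer
holding at least a floor fraction of the total signal (default 0.01).
The floor makes qualitative "permeated to X µm" statements
reproducible; it is configurable because it trades sensitivity
against noise-floor false positives.

## Synthetic sections

The generator emulates a treated, vertically sectioned skin specimen
at scan resolution: a 100×60 pixel grid at 50 µm, a 1 mm-thick band
whose midline follows a sinusoid (amplitude 250 µm, period 4 mm),
tissue pixels carrying three lipid-like peaks (m/z 184.073, 760.585,
782.567), a uniform marker peak at 104.107 (amplitude 500), and a
drug peak at 292.207 whose expected intensity is amplitude (1000)
times a depth-profile family; background pixels carry three distinct
contaminant peaks.  Band membership along depth is half-open, so a
band of thickness T occupies exactly T/pixel-size rows in every
column and the nominal layer widths are exact.

Profile families: `exponential` exp(−d/s) (superficial accumulation),
`half-gaussian` exp(−d²/2s²) (surface plateau with a deeper
shoulder), `delayed-peak` (d/s)·exp(1−d/s) (maximum at depth s,
sustained-release-like).  Default scale 150 µm, exponential.

Noise is multiplicative log-normal (σ = 0.25) per peak plus an
additive exponential floor (mean 5 counts, 0.5 % of the drug
amplitude) — chosen to be visible in single-pixel values while
leaving layer means estimable, the regime in which the tool is
useful.  The model deliberately omits DESI physics (desorption
plumes, carryover, Poisson ion statistics), spectral overlap between
channels, holes and tears in the section, and thickness variation
along the band.  Passing recovery tests therefore demonstrate the
pipeline's correctness on well-behaved data, not robustness to every
instrumental artifact; the manual cluster-selection and crop-box
escape hatches exist for the messier cases.

`true_profile` integrates the generating family over equal-depth
slabs (fine trapezoidal quadrature, 201 nodes per slab) and
normalizes by sum — the analytic oracle for pipeline recovery.

## Problem sizes and defaults used in the recovery study

Recovery statistics (tests and the acceptance script) use 20 sections
at the default spec with 10 layers of nominally 100 µm: the default
band is 20 pixels thick, so 10 layers give two pixel rows per layer —
enough stratification to resolve the 150 µm decay while keeping
per-layer means well estimated.  The 50-layer demonstration
configuration is exercised where it is exact, on a 50-row rectangle.
Observed recovery at these conditions: tissue-mask F1 = 1.0, profile
Pearson r > 0.99, depth-of-detection error of one layer width (the
additive noise floor biases the deepest detectable layer by one step
at the 1 % floor — an expected property of sum-normalized profiles
with a baseline, worth remembering when comparing real formulations).

## Known limitations

- Depth in the generator is vertical distance from the SC edge, a
  good approximation only for gently curved bands; per-column
  straightening likewise assumes curvature without folds or steep
  slopes (>45° to the scan axis).
- Equal-width layers are artificial strata; mapping them onto
  anatomical layers (epidermis/dermis) still needs histology.
- Profiles are relative (sum-normalized); no absolute quantitation.
- The pixel-table reader holds the full dataset in memory; scans far
  above ~10⁶ pixels would need a chunked reader (imzML support could
  be added behind the same dataset contract).
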