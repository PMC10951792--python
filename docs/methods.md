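# Methods

`celltyper` is a headless re-thinking of a common interactive
fluorescence-microscopy workflow: detect cells on a primary marker
channel, measure each cell on up to two further marker channels, and
assign user-defined cell-type labels by explicit rules. This note records
the models, conventions, and numerical choices the package commits to, and
what its synthetic validation does and does not demonstrate.

## Pipeline model

One channel, **Marker I** (typically a nuclear stain such as DAPI),
defines what a cell is. Segmentation runs only on that plane:

1. optional declarative preprocessing chain (segmentation only — see
   below);
2. global auto-thresholding of the 256-bin intensity histogram;
3. optional hole filling and binary watershed splitting;
4. 8-connected labeling with raster-ordered IDs and crack-boundary
   contour tracing.

**Markers II/III** are never segmented. Their intensity statistics are
measured inside each Marker I region, optionally eroded or dilated first,
and optionally augmented with a foci (bright-spot) count. Cells then pass
a relevance filter stage and a rule-based classifier; unmatched relevant
cells are labeled `unknown`, filtered-out cells `excluded`.

Preprocessing deliberately influences *segmentation only*: all intensity
features are measured on the raw planes, so measured statistics remain
comparable between runs that differ only in their conditioning chains.

## Coordinates, calibration, bit depth

* `x` = column, `y` = row, 0-based, origin top-left; every CSV repeats
  this in a header comment. When a region of interest is used, all
  reported coordinates are translated back into the original image frame.
* Spatial calibration multiplies length features by `pixel_width` and
  area features by `pixel_width * pixel_height`; dimensionless
  descriptors are computed on the pixel grid and are
  calibration-invariant.
* 8- and 16-bit planes are supported. 16-bit data keep full depth for
  intensity features; for histograms and thresholding they are rescaled
  onto 0–255 by `round(v * 255 / 65535)`, and the chosen level is mapped
  back to the native scale before binarization. This mirrors the common
  convention of running the classic 8-bit threshold algorithms on a
  256-bin histogram regardless of source depth.

## Auto-thresholding

Sixteen classical global methods are implemented from their published
definitions: Default (the legacy isodata/intermeans variant with the
moving-index stopping rule), Huang, Intermodes, IsoData, Li, MaxEntropy,
Mean, MinError(I), Minimum, Moments, Otsu, Percentile, RenyiEntropy,
Shanbhag, Triangle, and Yen. All return an integer level `t` with the
convention *foreground = pixels > t* (a `dark_background=false` flag flips
the comparison for inverted material). Choices worth noting:

* Ties in criterion-optimizing methods (Otsu, Yen, ...) go to the lowest
  level (first maximizer).
* Intermodes/Minimum smooth the histogram with a running 3-bin mean until
  exactly two modes remain (bounded at 10,000 iterations); Minimum then
  takes the first local minimum, Intermodes the mean of the two peaks.
* MinError(I) iterates the Kittler–Illingworth update from the mean
  threshold; if the quadratic degenerates (zero class variance, negative
  discriminant) the last stable level is returned.
* A single-occupied-bin (constant) histogram is an error: no threshold
  separates foreground.

The test suite re-derives every method from an independently coded
reference (exhaustive search where the method optimizes a criterion) and
requires exact agreement on random two-component histograms; Otsu, Yen,
IsoData, and Mean are additionally cross-checked against scikit-image.

## Segmentation conventions

* Foreground connectivity 8, background 4 (the standard dual pair).
* Labels are numbered 1..N in raster order of each component's first
  pixel, making IDs reproducible; no ordering is inherited from the
  labeling library.
* Watershed is the binary distance-transform variant: seeds are local
  maxima of the Euclidean distance map (quantized at 0.5 px so near-tie
  peaks merge), basins grow on the negated distance map, and the 1-px
  watershed lines are removed from the foreground. Foreground pixels are
  otherwise preserved, so the component count can only grow.
* Contours are crack boundaries over pixel corners, closed polygons whose
  shoelace area equals the pixel count; at diagonally-touching pixels the
  trace prefers the turn that keeps an 8-connected component in one loop.
* Hole filling is off by default and exposed as `segment.fill_holes`.

## Features

Shape: area, perimeter (corner-weighted crack length — the standard
weighted pixel-configuration estimate; bit-exact reproducibility is
promised within this package, parity with any other tool is not),
circularity `4*pi*A/P^2` clamped to 1, roundness `4*A/(pi*major^2)`,
aspect ratio, solidity, min/max Feret diameters (rotating calipers over
the convex hull of the boundary corners), ellipse axes and angle from
normalized second central moments, centroid, and bounding box.

Intensity (per marker, raw planes): mean, median, mode (lowest value among
ties), population standard deviation, min, max, integrated density
(mean x calibrated area), raw integrated density (plain sum), population
skewness, and excess kurtosis (both 0 by convention for zero-variance
regions). Population summaries use type-7 (linear-interpolation)
quantiles and the sample variance (n−1).

Columns are namespaced `M1.area`, `M2.mean`, `M3.foci_count`; unknown
feature names in any configuration fail fast with the list of valid names.

## Region resizing and foci counting

Erosion/dilation use a disk structuring element of configurable radius.
Dilated regions never invade a neighbouring cell's original pixels;
contested pixels go to the cell with the nearest original pixel set
(Euclidean distance, ties to the lower cell ID). A region emptied by
erosion is flagged and its marker features recorded as missing.

Foci are counted with an intensity-prominence criterion. The `tolerance`
parameter (default 30) is an intensity drop, not a distance: a local
maximum counts as a distinct focus iff it cannot be reached from any
higher maximum without descending by at least `tolerance` levels
(flood-fill test restricted to the cell region). Equal-valued maxima
joined by such a flood merge into one focus at the seed plateau's
centroid; a perfectly flat region contains no foci. One consequence worth
stating plainly: any *non*-flat region has at least one focus (its global
maximum has unbounded prominence), so on noisy renderings a zero-spot
nucleus still reports one. The ground-truth recovery checks therefore run
on ideal (noiseless) renderings, where zero-spot nuclei are exactly flat;
the classification-level checks (the "at least 8 foci" rule) run at the
default noise level, where single spurious maxima are irrelevant.
An optional pre-smoothing sigma (default off) is exposed for noisy real
material.

## Classification

Filters and interval constraints use inclusive bounds; cross-feature
comparisons (`M2.mean > M1.mean`) support strict and non-strict relations
explicitly. Types are evaluated in definition order and the first full
match wins; since the rules language allows overlapping definitions, a
diagnostic `all_matching_types` column records every satisfied type.
Quartile-based recipes ("circularity in Q4" ⇔ value ≥ Q3) are expressed
with symbolic bounds `Q1(feature)`/`Q2(...)`/`Q3(...)` in the XML, and are
re-resolved against the relevant cells of *each* image in batch mode, so
batch runs stay adaptive per image. Quadrant counts treat a value equal to
the threshold as "high". Curve fits (linear, polynomial, power,
logarithmic, exponential) use least squares; power and exponential are fit
by log-linearization (hence require positive data) and R² is always
reported on the original scale.

## Configuration and batch mode

The XML schema is defined by this package (`schema_version` 1.0),
deliberately flat and hand-editable, and validated before any pixel is
touched: unknown elements/attributes are rejected by name, as are
constraints on unmapped markers or disabled foci columns. Batch mode
processes a directory in lexicographic filename order, isolates per-image
failures into the set summary, and is required (and tested) to be
byte-identical to per-image runs; CSV values print at 6 significant
digits so repeated runs are byte-identical.

## Synthetic scenes

The generator places hard ellipses by rejection sampling with a minimum
separation, paints constant interior intensities per marker, plants
Gaussian foci with a minimum mutual separation, and adds clipped additive
Gaussian noise; all randomness flows from one seeded generator. Default
study conditions: 512x512 frames, background level 10, nuclei of radius
8–14 px at intensity 150–220 with noise sigma 3 (the `nuclei` preset);
the `foci` preset uses 50 nuclei with Marker I at 55–70, Marker II base
85–105 (so the cross-marker rule holds in every cell), 0–12 spots of
amplitude 100 and sigma 1.2 at ≥ 5 px separation, noise sigma 2; the
`spirochete` preset mixes five shape families (large round blood cells,
round/elongated/small/normal bacteria, 40 objects) whose intended classes
are assigned by evaluating the same quartile recipe on the planted pixel
sets, making "exact partition recovery" well defined.

Problem sizes in the test suite (10–50 cells per scene, 256–512 px
frames, 2–20 seeds per property) were chosen so each check exercises the
full pipeline while the whole suite stays interactive to run.

What passing these tests shows: the geometry, bookkeeping, and rule
machinery are exact on material whose ground truth is known, and stable
under modest additive noise. What it does not show: performance on real
microscopy with PSF blur, shot noise, uneven illumination, textured
chromatin, or dense overlapping cells — on such material segmentation
quality is governed by the chosen threshold method and preprocessing
chain, exactly as in the interactive tools this package mirrors.

## Known limitations

* Only single-plane TIFF/PNG input; no multi-series containers,
  z-stacks, or time series.
* Global thresholding only; no local/adaptive or learned segmentation.
* The foci tolerance is prominence-based; a distance-suppression variant
  is not implemented.
* Shape features are never recomputed on Markers II/III (geometry belongs
  to Marker I by design).
* CSV is the only tabular output format.
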