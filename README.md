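# celltyper

Headless, scriptable detection and rule-based classification of cells in
2D multi-channel fluorescence images.

Many imaging experiments reduce to the same question: *how many cells of
each kind are in these images?* — where "kind" is something a biologist
can state as explicit rules ("nuclear area at least 5 px, mean p21 signal
above the DAPI mean, at least eight γH2AX foci"), not something that needs
a trained classifier. `celltyper` is for exactly that setting: it detects
cells on a primary marker channel, measures every cell on up to three
channels, applies user-defined constraints, and scales the whole analysis
to directories of images from a single editable XML configuration — with
no GUI, so runs are reproducible and testable.

## The model

One channel, **Marker I** (e.g. a DAPI nuclear stain), defines what a
cell is. Its plane is optionally preprocessed, binarized with one of 16
classical global auto-threshold methods (Default, Huang, Intermodes,
IsoData, Li, MaxEntropy, Mean, MinError(I), Minimum, Moments, Otsu,
Percentile, RenyiEntropy, Shanbhag, Triangle, Yen), optionally hole-filled
and watershed-split, and labeled into cells with unique IDs. Each cell is
described by shape descriptors — area *A*, perimeter *P*, circularity
4π·A/P², roundness 4A/(π·major²), aspect ratio, solidity, Feret diameters,
fitted-ellipse axes — and per-marker intensity statistics (mean, median,
mode, SD, min/max, integrated densities, skewness, kurtosis), calibrated
to physical units when a pixel size is given.

**Markers II/III** are measured inside each detected region (optionally
eroded or dilated first). A *foci-per-nucleus* analysis counts bright
spots per cell as intensity local maxima filtered by prominence: a
maximum is a distinct focus iff it cannot be reached from a higher
maximum without descending by at least `tolerance` (default 30) intensity
levels.

Cells passing every **relevance filter** (inclusive min/max on any
Marker I feature) are classified by the first **cell type** whose
constraints all hold — interval constraints on any feature, cross-marker
comparisons such as `M2.mean > M1.mean`, or per-image quartile bounds
such as `circularity ≥ Q3(circularity)`. Unmatched cells are `unknown`,
filtered cells `excluded`. Reports include per-cell tables, descriptive
summaries, scatter data, quadrant counts for any feature pair, and curve
fits (linear/polynomial/power/logarithmic/exponential).

A built-in synthetic-scene generator (`celltyper synth`) renders
multi-channel images with fully known ground truth — positions, pixel
sets, intensities, planted foci, intended classes — so every stage of the
pipeline is testable without any dataset.

## Worked example

Generate a synthetic "foci" scene (50 nuclei; Marker II carries 0–12
planted bright spots per nucleus), then apply the classic two-condition
rule — Marker II mean above Marker I mean *and* at least eight foci:

```bash
celltyper synth --preset foci --n 1 --seed 3 --out imgs
# wrote imgs/foci_0003.tif (50 cells)

celltyper analyze --image imgs/foci_0003.tif --config foci.xml --out out
# foci_0003.tif: 50 cells, 50 relevant; positive=10, unknown=40
```

All 50 nuclei are detected and pass the area filter; exactly the 10 cells
whose planted foci count is ≥ 8 are labeled `positive` — matching the
generator's ground truth (`imgs/foci_0003_truth.csv`). The output folder
contains `cells.csv` (one row per cell, features namespaced `M1.area`,
`M2.mean`, `M2.foci_count`, ...), `classification.csv`, and `summary.csv`.

The configuration is plain XML, written with `save_config` or by hand:

```xml
<celltyper-config schema_version="1.0">
  <channels markerI="0" markerII="1" />
  <segment method="Otsu" watershed="false" fill_holes="false" dark_background="true" />
  <markerII>
    <resize mode="none" radius="1" />
    <foci enabled="true" tolerance="30.0" presmooth_sigma="0.0" />
  </markerII>
  <filters>
    <filter feature="M1.area" min="5.0" max="inf" />
  </filters>
  <cell_types>
    <cell_type name="positive" color="255,0,0">
      <constraint left="M2.mean" relation="&gt;" right="M1.mean" />
      <constraint feature="M2.foci_count" min="8.0" max="inf" />
    </cell_type>
  </cell_types>
</celltyper-config>
```

`celltyper batch --in DIR --out DIR --config cfg.xml` runs the same
analysis over every TIFF/PNG in a directory (lexicographic order, one
output folder per image, a set-level `batch_summary.csv`, per-image
failures isolated and recorded).

## Layout

- `src/celltyper/imgio.py` — loading, marker–channel matching, calibration, ROI, histograms
- `src/celltyper/thresholds.py` — the 16 global auto-threshold methods
- `src/celltyper/preprocess.py` — declarative conditioning chain (segmentation only)
- `src/celltyper/segment.py` — binarization, hole filling, watershed, labeling, contours
- `src/celltyper/features.py` — shape/intensity features and summaries
- `src/celltyper/regions.py` — region resizing and foci counting
- `src/celltyper/classify.py` — filters, cell types, quartiles, quadrants, curve fits
- `src/celltyper/config.py`, `batch.py` — XML configuration and single/batch execution
- `src/celltyper/synthgen.py` — ground-truth synthetic scenes
- `docs/methods.md` — conventions, formulas, and design decisions in detail
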