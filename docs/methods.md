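# Methods

This note records the models, conventions and numerical choices behind
`focicount`, in the order the pipeline applies them, plus what the
synthetic-image generator does and does not emulate.

## Image model and conventions

Images are single-plane, 8- or 16-bit unsigned grayscale rasters in the
bright-on-dark convention (light-background images are complemented,
pixel → 2^depth − 1 − pixel, an exact involution). Coordinates are
0-based and row-major with x = column, y = row; pixel centers sit at
integer coordinates. At most three channel roles exist — `roi` (nuclear
stain), `foci1`, and optionally `foci2` — so two distinctly labeled
repair markers can be scored against one nuclear counterstain. Loading
never alters pixel values; there is no contrast adjustment, blurring or
sharpening anywhere in the pipeline, so exported intensities are raw
camera values.

Per-channel files are grouped by a filename token (default `_c{index}`).
This pairing rule is a package convention; incomplete groups are reported
in the skipped-inputs manifest, never silently analyzed.

## Segmentation

* **Threshold.** Foreground is `pixel ≥ t` (the threshold value itself is
  foreground, so manual thresholds are exactly reproducible). Automatic
  `t` comes from the image histogram: isodata (intermeans fixed point,
  the default) or Otsu. When the isodata criterion admits several fixed
  points — common when nuclei occupy a small area fraction, because the
  background noise distribution supports its own fixed point — the
  highest one is used: it is the one separating the bright class from
  everything darker. The chosen value is logged and exported. A constant
  raster has no separable histogram and raises a degenerate-image error
  naming the file.
* **Fill holes** (optional, default on): background regions not connected
  to the image border become foreground. Idempotent, never removes
  foreground.
* **Watershed separation** (optional, default off): per connected
  component, seeds are local maxima of the Euclidean distance transform
  at least 4 px apart; a component splits only when it has ≥ 2 seeds, so
  a single convex object is never fragmented. Every foreground pixel
  keeps exactly one label. Elongated or very noisy masks can in principle
  acquire extra distance-transform peaks; the 4 px seed separation is the
  guard against over-segmentation.
* **Labeling and filters.** Objects are 8-connected. Each object gets
  area (pixel count), perimeter (Crofton 4-direction estimate — pinned
  because circularity depends on the estimator; the test suite checks it
  against an independent boundary-walk trace), circularity
  min(1, 4π·area/perimeter²) (capped because rasterization can push tiny
  objects above 1), centroid, and a border flag (any pixel on the
  outermost row/column). Filters: min/max area, min/max circularity,
  optional edge exclusion. Survivors are renumbered 1..n in ascending
  label order; per-filter drop counts are reported.

## Foci detection

A focus is an accepted local maximum of the foci channel inside an ROI.
For a candidate maximum m with value v and noise level τ (the
user-facing tolerance), the merged region R(m) is the connected set of
ROI pixels reachable from m through pixels of value > v − τ. m is
accepted iff R(m) contains no pixel brighter than v. Pixels outside the
ROI are treated as −∞, so signal outside a nucleus can neither create
nor suppress a focus inside it.

Pinned determinism rules:

* local maxima use the 8-neighborhood;
* a plateau of equal-valued maximal pixels yields one focus at the
  plateau pixel nearest the plateau centroid (ties by smallest (y, x));
* a plateau with no strictly lower in-ROI neighbor (a constant ROI) is
  not a peak and yields nothing;
* among equal-valued maxima merged into one region, the representative
  with the smallest (y, x) survives;
* τ = 0 accepts every plateau individually.

Foci are integer pixel positions with their raw peak value; there is no
sub-pixel localization. The optional per-channel cutoff deletes accepted
foci with peak < cutoff (≥ keeps a focus exactly at the cutoff); it is
applied before all counts, densities and colocalization, one consistent
rule. Foci are deliberately **not** split by intensity watershedding:
that would require 8-bit reformatting and lose intensity information, so
overlapping foci closer than the merge scale count as one — the known
undercount at high damage density shared with manual scoring.

The detector is verified against an independent pure-Python flood-fill
oracle on hundreds of random rasters (exact set equality), and carries
monotonicity (counts non-increasing in τ and cutoff), shift-invariance
and locality property tests.

## Measurement and outlier exclusion

Per ROI: area, mean/min/max intensity over exactly the ROI's pixels
(measured on the nuclear-stain channel by default, configurable to a
foci channel), foci counts, and the area-corrected density
count / area × factor. The factor (default 1000, i.e. foci per 1000 px²)
rescales the per-pixel density to a readable magnitude; when a pixel
size in µm is configured, densities become per-µm²-based instead.

The percentile option excludes outlier nuclei — typically S-phase cells
whose replication-associated signal mimics damage foci. Per image, the
nearest-rank p-th percentile (the ⌈p/100·n⌉-th order statistic) of the
per-ROI focus count is computed; ROIs strictly above it are flagged.
Flagged rows stay in the per-ROI export and are only omitted from
summary statistics, so no focus is ever silently lost. Direction,
variable and method are package conventions (the underlying idea is
stated only loosely in the field); they are pinned here and tested.

## Colocalization

Within one ROI, foci of the two channels are paired one-to-one, greedily
by ascending Euclidean distance between peak positions, keeping pairs
with distance ≤ tolerance; equal distances break lexicographically on
(x1, y1, x2, y2). Greedy matching is deterministic and, at biological
foci spacings (partners near, decoys far), reaches the maximum possible
pair count — verified against exhaustive maximum-cardinality matching on
every small instance in the test suite. On adversarial dense
configurations greedy can differ from the optimum; the greedy rule is
the pinned contract. Percentages are 100·pairs/foci per channel (0 when
a channel is empty); image summaries pool totals rather than averaging
per-ROI percentages. Colocalization always operates on post-cutoff foci.

## Batch, aggregation and export

All images under the input root (recursive, deterministic lexicographic
order) are analyzed independently; one failure never disturbs another
image's rows, and a zero-ROI image is a warning, not an error. The
per-image table holds ROI counts, the chosen threshold, total and mean
foci (over non-flagged ROIs) and coloc summaries. The batch summary has
two labeled rows: `mean_of_images` (unweighted mean over images — each
image counts once) and `pooled_over_rois` (every ROI weighted equally).
Both are exactly recomputable from the next-lower table, which the test
suite asserts byte-for-byte alongside rerun determinism. CSV is the
canonical format (UTF-8, header row, `.` decimal, `\n` line ends);
xlsx mirrors the CSVs sheet per table. Timestamps appear only in
`run_metadata.json`.

## Synthetic images

The generator emulates the assay geometry: bright filled ellipses
(nuclei) on a dark background; foci as 2-D Gaussian bumps of given
amplitude and σ at integer positions inside the nuclei, with a minimum
spacing; optional second channel with a planted colocalized fraction
(partner offset ≤ 1 px by default, `round(fraction × n)` pairs) and
decoy foci kept ≥ 10 px from every channel-1 focus (decoys may land in
any nucleus with room — the exclusion zones can crowd out a single
nucleus); additive Gaussian noise (optional Poisson term behind a flag);
clipping and 8/16-bit quantization; optional light-background
inversion and an optional intranuclear intensity gradient to stress
auto-thresholding. Identical spec + seed gives bit-identical output.

Default study conditions: 448×448 px, 5 nuclei of semi-axes 18–30 px,
nuclear plateau 90 above a background of 20, focus amplitude 60 at
σ = 1.6 px, focus spacing 7 px, noise σ = 6 (amplitude = 10σ). The
matching analysis settings used throughout tests and examples are noise
level 24 (4σ) and cutoff 140 (background + nucleus + half the focus
amplitude — between the nuclear noise ceiling and the focus peaks, which
is how a practitioner sets a cutoff to kill background maxima). Dose
series draw per-nucleus focus counts Poisson(rate × dose) — the field's
linear dose response at ~15–19 foci/Gy — using larger nuclei (semi-axes
42–50 px) so that ~50 foci fit at the minimum spacing.

Not modeled: optics (PSF tails, defocus), camera gain/readout structure,
chromatin texture, overlapping foci blobs beyond Gaussian addition, and
3-D stacks. Recovery results on these images therefore bound the
*algorithmic* error of the pipeline under the stated SNR and spacing;
they do not certify performance on crowded, low-SNR real micrographs,
where parameter choice (threshold, noise level, cutoff) dominates.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use: 100 random 32×32 rasters
for the maxima oracle; 1/5/20 planted nuclei over 20 (tests) or 10
(script) seeds; 50/30 images of 25 planted foci for recall/precision;
one 1280×1280 image of 40 nuclei per dose for the dose fit; and
50/20 seeds per colocalized fraction. These sizes make the entire check
suite run in well under a minute per stage on one CPU while keeping
every pooled estimate over hundreds of objects.

## Known limitations

* Merged (overlapping) foci count as one; no intensity watershedding.
* Single-plane only; no z-stacks, time series or 3-D objects.
* Open formats only (TIFF/PNG); vendor formats must be converted.
* Automatic thresholds are histogram-global; no local/adaptive
  segmentation, and heavily crowded fields should use watershed plus
  conservative circularity filters or be excluded.
* The percentile filter assumes outliers are *high* counts.
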