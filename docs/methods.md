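# Methods

## Assay model

The package quantifies genotoxicity from two-channel wide-field fluorescence
images of a 96-well plate. The DNA counterstain (DAPI/Hoechst) defines where
nuclei are; the Cy3 channel carries the γH2AX immunofluorescence whose
overall intensity tracks DNA double-strand breaks. Viability is not measured
directly: non-adherent (dead) cells wash off during staining, so the mean
segmented-nucleus area of a well, relative to control (RA), serves as the
cytotoxicity proxy that relative cell counts provide in flow cytometry.

The per-condition endpoint is the fold change of the area-normalised signal,
MoA = MFV_mean / Area_mean, treated over control, classified against a
1.5-fold genotoxicity threshold with a 25 % RA evaluability limit.
The classification grid leaves two cells undefined: fold exactly at
threshold with RA < 25 % (reported NOT_EVALUABLE with a warning) and
fold > 1.5 with RA exactly at 25 % (reported EQUIVOCAL). RA > 100 % is
legal and classified by the same rules. Equality is decided within 1e-9.

## Segmentation

* **Otsu convention.** 256-bin histogram spanning [min, max] of the image
  (the ImageJ auto-threshold convention for >8-bit data); between-class
  variance is maximised over all bin splits, ties broken toward the lowest
  bin; the returned scalar is the largest pixel intensity of the background
  class, so "foreground = strictly greater than threshold" reproduces the
  bin split exactly on any dtype. Constant images raise an error and fail
  the well softly (the well is logged and its condition reported
  NOT_EVALUABLE), never silently zeroed.
* **Threshold propagation.** The production behaviour computes the threshold
  on the lexicographically first field of a well and reuses it for all 16
  fields, reproducing the save-and-reuse behaviour of acquisition-time
  macros; `per_well_pooled` (threshold on the concatenated histogram) and
  `per_image` are selectable. The mode and each threshold are recorded in
  the run log.
* Connected components use 8-connectivity; objects touching the border are
  removed and labels compacted. No size filter and no hole filling by
  default; both exist as options. Nothing splits touching nuclei — the
  synthetic generator therefore plants non-overlapping nuclei so that tests
  measure the pipeline, not a declumping step it does not have.

## Background subtraction

The Cy3 background is the grayscale opening of the image with a ball
(sphere-cap) structuring element of radius 50 px: the envelope traced by a
ball rolled under the intensity surface. This is an exact definition with
testable semantics — output = input − opening, clipped at 0; the opening is
idempotent, bounded by the input, and invariant to additive offsets. The
implementation composes two passes of scikit-image's fast sliding-kernel
engine (erosion, then dilation as the negated erosion of the negation) and
is verified against a brute-force opening oracle. Values can differ slightly
from ImageJ's legacy sliding-paraboloid approximation; fold and RA are
ratios and are insensitive to this. Near the image border the ball overhangs
the edge (outside pixels are ignored), leaving a small residual on steep
gradients there. An optional 3×3 mean pre-filter (off by default) tames the
noise-driven downward bias of the estimate on very noisy images. Subtraction
applies to Cy3 only, never to DAPI.

## Well statistics

Objects are pooled over all fields of a well without per-field averaging.
Mean and IQR (linear-interpolation quantiles) are reported; the mean feeds
MoA because the scoring is defined on means, while the median is exported
for inspection. The D'Agostino–Pearson omnibus test (skewness + kurtosis,
n ≥ 8) documents non-normality per feature; it justifies reporting IQR
instead of a standard deviation and never gates any computation.

## Synthetic plates

The generator emulates the acquisition: per well, `fields_per_well` (default
16, i.e. 4 × 4) field pairs of `image_size` (default 512 × 512) pixels at
2.6 µm/px (650 nm camera pixels, 4 × 4 binning). Per field it rejection-
samples non-overlapping ellipses (radius ~N(6, 1) px clipped at 2, axis
ratio uniform in [1, 1.5], area-preserving), renders them into DAPI with a
Gaussian edge blur (σ = 1 px), and gives each nucleus a flat log-normal Cy3
amplitude (median 300, σ_log = 0.5) — flat so that the ground-truth in-mask
mean equals the drawn amplitude. Cy3 additionally receives a constant
pedestal (100) plus a planar gradient (40 peak-to-peak); both channels get
Poisson shot noise and Gaussian read noise (σ = 5). Defaults put pooled
well totals near 2000 objects, inside the 1000–3000 range typical of real
wells. A fixed seed yields byte-identical plates; each field has its own
seed stream derived from (seed, well, field), so generation order is
irrelevant.

Treatment effects are multiplicative. `area_scale` scales per-nucleus area,
`count_scale` the expected count. `cy3_gain` is defined as the *designed
fold of the MoA endpoint*: the rendered per-pixel amplitude is multiplied by
`cy3_gain × area_scale`, so a perfect pipeline recovers fold = `cy3_gain`
and RA = 100 × `area_scale`. This makes the generator's dial speak the same
language as the assay readout.

What the generator does not emulate: optics-accurate PSFs, apoptotic or
mitotic morphologies, touching/overlapping nuclei, vignetting beyond a
planar gradient, or focus errors. Passing tests therefore demonstrate the
correctness of the measurement chain under controlled conditions, not
robustness to every real-data pathology.

## Benchmark experiments and problem sizes

* **Segmentation ground truth** uses a noise-free well (16 fields, 512²) of
  50 uniform-amplitude disks of radius 12 px per field, no blur and no
  background: counts and edge exclusion must be exact and each area within
  5 % of the analytic ellipse area.
* **End-to-end recovery** uses the frozen `low_noise_benchmark_config`:
  three wells (control; treated with designed fold 3.0, area scale 0.7,
  count scale 0.8; sham with fold 1.0 at the same cytotoxicity), 16 fields
  per well at 256², ~45 nuclei of ~8 px radius per field, read noise only
  and narrow amplitude spreads (σ_log = 0.2, DAPI σ = 300). The reduced
  field size and object totals keep the experiment desk-scale while leaving
  effect sizes untouched. Across seeds the recovered fold sits at 2.78–2.97
  (designed 3.0) and RA at 71–72.5 % (designed 70 %); the ~2 % downward fold
  bias is edge dilution — the DAPI-derived mask includes blurred boundary
  pixels whose share grows as nuclei shrink — and is inherent to
  mean-intensity readouts at this resolution.
* The published valinomycin well means shipped in `h2axquant.benchmarks`
  round-trip through MoA/fold/RA within 1 % (the printed inputs are rounded
  to 3–4 significant digits; one printed fold value, 13.200, recomputes to
  ≈13.11 from the printed means because the original computation used
  unrounded values).

## Numerical conventions

* Quantiles: linear interpolation (numpy default); IQR depends on it.
* Foreground: strictly greater than threshold, everywhere.
* Otsu ties: lowest qualifying bin.
* Areas: pixel count × calibration²; calibration is configurable because
  absolute areas depend on it while RA and fold do not.
* CSVs: '.' decimals, ',' delimiter; reruns on identical inputs are
  byte-identical (the run log's timestamp line excepted).
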