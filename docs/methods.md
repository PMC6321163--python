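# Methods

This note documents the models, estimators and numerical choices behind
`fibriltrace`, and what validation on synthetic scenes does and does not
establish about real AFM data.

## Background flattening

Raw tapping-mode topographs carry three background terms that dwarf the
~1–3 nm aggregate heights: overall substrate tilt (a plane), scanner bow (a
smooth quadratic warp along the fast-scan axis), and per-scan-line offsets
from feedback drift. The chain is:

1. global least-squares plane subtraction, then per-row median subtraction;
2. feature masking: pixels above `median + mask_k · 1.4826 · MAD` of the
   whole image are excluded from background fitting. The robust threshold is
   a reproducible surrogate for the by-eye threshold an operator would
   choose; `mask_k` defaults to 3 (≈ 3σ for Gaussian background). Because
   the centre is the median, the mask can never cover a majority of pixels;
   downstream fits additionally refuse any user-supplied mask leaving less
   than 10% background.
3. per-row second-order polynomial fit to unmasked pixels, subtracted from
   the entire row. The column coordinate is rescaled to [−1, 1] so the
   normal equations stay well conditioned at 1024 px. Rows left with fewer
   than `order + 2` background pixels (e.g. crossed end-to-end by a fibril)
   reuse the element-wise median of the well-fitted rows' coefficients
   rather than being destroyed by an unconstrained fit.
4. the mask → flatten round runs `n_passes` times (default 2): the second
   pass recomputes the mask on the improved background, which stabilises it
   when the initial tilt or bow is large. On an exactly polynomial
   background the chain is exact to numerical precision and idempotent.

**Background model.** A Gaussian `A·exp(−(h−μ)²/2σ²)` is fitted to the
histogram of background pixel heights — 256 bins spanning the 0.1–99.9
percentile range (clipping keeps stray feature pixels from stretching the
bins) — by Levenberg–Marquardt from moment-based starting values. μ defines
the height zero and σ the noise scale for detection. On fit failure the
sample median and MAD-σ are used and flagged with a warning; a perfectly
constant background (possible only in synthetic data) is passed through with
σ = 0 and `fit_converged=False`, and detection refuses to threshold it.

## Detection and morphometry

Detection thresholds the flattened image at `k_detect · σ` (default 5,
i.e. a per-pixel false-positive rate ≈ 3·10⁻⁷) and labels 8-connected
components; clusters below `min_area_px` (default 4) are discarded as noise.
4-connectivity would split diagonal fibril paths, hence 8. Features that
touch or overlap merge into one object; this over-merging is accepted and
applied identically to every condition, so between-condition trends remain
comparable even where absolute values are inflated.

Per-feature estimators:

* **Length** — the skeleton (morphological thinning) is decomposed into
  ordered pixel chains between endpoints and junctions; each chain's length
  is the polyline length after smoothing interior pixels with a 5-pixel
  moving average (endpoints fixed). Raw step counting (1 per orthogonal,
  √2 per diagonal step) overestimates obliquely oriented smooth curves by
  up to ~8% — the classic staircase bias — which the smoothing removes
  (residual error ≤ ~1.5 px across orientations). Each free end is extended
  to the object boundary by marching along the local skeleton direction,
  since thinning stops roughly half a width short of the tip and the
  lateral distance transform underestimates that gap for thin oblique
  objects. Branch lengths of a branched skeleton are summed: a fibril with
  outgrowths or overlaid arms counts once, with the combined length of all
  branches. Features whose skeleton collapses to ≤ 2 pixels (compact blobs)
  use the maximum Feret diameter — for a round object the "long axis" is
  the natural reading. Geodesic (along-curve) length is used for curved
  fibrils rather than end-to-end distance; for straight objects the two
  coincide.
* **Width** — `max(2·(mean EDT on skeleton) − 1, area/length)` pixels. The
  medial-axis term is exact for well-resolved rods (the −1 converts
  centre-to-background-centre distance to the boundary-to-boundary
  convention); the area-per-unit-length term takes over for objects only
  2–3 px across, where the discrete EDT collapses. Compact blobs use the
  equivalent-disc diameter `2·sqrt(area/π)`.
* **Max height** — maximum in-cluster pixel height relative to μ. The
  maximum is chosen deliberately over the cluster mean, which would
  understate fibril peak height; it is exposed to single-pixel noise, but at
  the default 5σ threshold and ~0.1 nm noise the positive bias is a few
  percent of a 2 nm fibril.
* **Class** — fibril iff length ≥ 2 × width, else oligomer. The boundary is
  exact and deliberately simple; near-threshold objects flip class with
  single-pixel footprint changes, which is why condition statistics pool
  many features.
* **Edge handling** — features touching the image border are measured but
  flagged and excluded from length/height statistics (their true extent is
  unknowable); they still count toward coverage.

Surface coverage is the percentage of pixels above threshold after the
min-area filter, counting fibrils and oligomers together.

## Aggregation

Length and height statistics pool features across a condition's images
(SEM = sd/√n_features): features are the measurement unit, and a condition
contributes thousands of them. Coverage is defined per image, so its mean
and SEM use images as replicates. Zero usable fibrils raises an explicit
"no fibrils" error rather than reporting zero. Error bars are SEM and are
labelled as such in all outputs. Length distributions use a Gaussian-kernel
KDE with Silverman's bandwidth (`(3n/4)^(−1/5)·sd`), evaluated on an even
grid spanning the data range ± 3 bandwidths; the trapezoid integral is 1
within 1%. No hypothesis testing is performed — the analysis reports means,
errors and ratios only.

## Synthetic scenes

The generator emulates the statistical structure of the real experiment,
not its physics:

* **Fibrils**: discrete worm-like chains, fixed 5 nm steps, turning angles
  N(0, √(2Δs/P)) so the tangent correlation decays as e^(−s/P) and the
  Kratky–Porod relation ⟨R²⟩ = 2PL − 2P²(1 − e^(−L/P)) holds (verified
  against the closed form within 5%). Default persistence length 1500 nm,
  typical of mica-adsorbed amyloid fibrils. Painted as flat-topped,
  butt-capped ridges of sampled height (default ~2 ± 0.25 nm) and apparent
  width 20 nm (tip-broadened). Lengths are log-normal (median, geometric
  sd), truncated below at 50 nm so every ground-truth "fibril" satisfies
  the operational length ≥ 2 × width definition, and above at 35% of the
  scan so each fits the field.
* **Oligomers**: parabolic-cap bumps, radius 15 ± 3 nm (floored at 1.5 px)
  and peak height 1.8 ± 0.3 nm, keeping default scenes above the detection
  limit.
* **Background and noise**: plane tilt (3–4 nm across the field), 1.5 nm
  quadratic bow along the fast axis, per-line offsets (σ = 0.15 nm),
  additive pixel noise σ = 0.1 nm — typical tapping-in-air values — and
  Gaussian tip blur (σ = 0.5 px) applied to the ideal topography before
  noise.
* **Placement**: objects are placed with a guaranteed 3 px separation
  (rejection sampling; an infeasibly crowded spec raises an error), so each
  painted object maps to one connected component and object-level
  truth-vs-measurement comparison is well defined. Overlap handling
  (summed heights capped at 1.5× the tallest object) therefore only
  concerns a fibril's self-crossings, which take the pixel maximum.
* **Condition grid**: 3 DHA concentrations × 3 incubation times × 8 images.
  Length medians rise with time within each concentration, keep the
  30 < 0 < 100 μM ordering at every time point, and reach 126/250/421 nm at
  24 h; heights and object counts follow the same trend. Per-image seeds
  derive deterministically from one grid seed; identical arguments give
  bit-identical datasets.

What passing synthetic validation shows: the flattening is exact on its
model class, the background fit is calibrated, and the morphometry recovers
known lengths, widths, heights, counts and coverage through the entire
pipeline (per-condition mean length within 10% of truth, coverage within 1%
absolute, ordering preserved). What it does not show: robustness to real
tip asymmetry and double-tip artifacts, scars/streaks, drift shear,
substrate contamination, or dense mats where merging dominates — none of
which the generator models. Absolute lengths on real data also retain the
over-merging bias discussed above.

## Problem sizes and runtimes

Validation and the acceptance script run the grid at 512² px over 5 × 5 μm —
the same 9.77 nm/px pixel size and object density as the default 1024² px,
10 × 10 μm field, at a quarter of the area (object counts scale with area;
pooled fibril counts per condition stay ≥ ~90, keeping the sampling SEM of
condition means near 2–3%). The full 72-image grid generates and analyses
in well under a minute on one CPU; 1024² fields cost about 4× per image.

## Known limitations

* Lengths of merged aggregates are reported as single combined objects by
  design; no attempt is made to separate touching fibrils.
* No tip deconvolution: widths are apparent (tip-broadened) widths.
* The Feret fallback underestimates the curve length of small bent objects
  (they are classified oligomer anyway).
* The Gaussian background model assumes unimodal, roughly symmetric noise;
  heavily contaminated substrates violate it and trigger the median/MAD
  fallback.
* Proprietary instrument files are not parsed; convert to float TIFF or
  ASCII matrices first (heights in nm).
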