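# Methods

## The measurement problem

Primary leukemia blasts in a collagen/stroma co-culture cannot be
counted by fluorescent viability dyes without perturbing them, and they
barely translate — the collagen pins their positions.  What separates
a live blast from a dead one under transmitted light is *membrane
motion*: a live, non-adherent cell renders as a bright cytoplasmic disc
outlined by a dark membrane ring, and that ring wobbles a little every
frame; upon death all motion ceases.  The pipeline turns a per-well
bright-field time-lapse (nominally 2,048 × 1,536 px, one frame every
30 min for 96 h, i.e. 192 frames) into a per-frame *live pixel area*,
then into normalized viability, and finally into per-drug LD50 and AUC
summaries.

## Detection pipeline

Per well, in order:

1. **Registration** (translational only).  Consecutive frames are
   aligned by Fourier phase cross-correlation, estimated
   frame-to-previous and accumulated ("chain" mode; "reference" mode
   available).  Shifts are applied by *linear* sub-pixel interpolation
   with replicate-edge fill — higher-order splines and Fourier shifts
   overshoot at the sharp disc/ring edges, and the phase-dependent
   overshoot later reads as motion.  Two safeguards: a frame whose
   bright structure does not exceed 4× its sensor noise contributes no
   shift (correlating noise yields a random-walk drift), and a frame is
   only resampled once its estimated shift departs from the currently
   applied one by more than a 0.1-px deadband, so estimator jitter does
   not smear static content.
2. **Uniform pre-smoothing** (Gaussian, σ = 0.75 px).  Sub-pixel
   resampling softens a frame by an amount that depends on the
   fractional shift; smoothing every frame by one small fixed kernel
   makes that softening uniform so it cannot masquerade as motion.
3. **Background flattening**: grayscale morphological opening with a
   disc wider than a cell (default 50 px at the reference 5× scale,
   3 cell radii in the reduced test geometry), subtracted from the
   frame.  The opening slides under cell-scale bright structure but
   follows smooth illumination, so cells stand on a near-zero
   background.
4. **Running maximum projection** over a trailing window of W = 6
   frames (3 h at 30-min spacing).  Anywhere a membrane has been
   during the window stays bright in the projection.
5. **Motion difference**: projection minus current frame, clipped at
   zero.  Static content cancels exactly; moving membranes leave
   bright rings.  The first defined value therefore falls at frame
   index W (time point 6, 3 h), once a full window precedes it.
6. **Rings → spots**: Gaussian blur (σ = cell_radius/5, ≥ 1 px), then
   *hysteresis* binarization, then hole filling bounded at
   2π·cell_radius² (ring-interior scale), then the summed pixel count.
   Area, not cell count, is the viability signal — no segmentation of
   touching cells is needed.

### The threshold, in detail

The strong threshold is `max(k_abs, k_rel · S)` with `k_rel = 0.12`.

* `S` is the *cell-brightness plateau* of the background-subtracted
  frame: the median of pixels above half its 99.9th percentile.  Cells
  persist whether alive or dead, so `S` is stable from frame to frame,
  tracks global intensity rescaling (making the mask scale-invariant),
  and — unlike a fixed image-wide percentile — barely moves when more
  cells of the same brightness enter the field.  Anchoring the
  threshold to an extreme order statistic of the difference image
  itself (the obvious alternative) couples the threshold to the signal
  being thresholded and destabilizes the area trace.
* `k_abs` is a floor at 3× the sensor noise, estimated robustly from
  adjacent-pixel differences of the unsmoothed frame.  It is
  irrelevant wherever cells set the relative term and decisive in
  empty wells, where the relative term collapses.
* Pixels above the strong threshold seed detections; connected pixels
  above half of it delimit each spot's extent.  A single threshold
  leaves arc gaps where the membrane happened to sit at the window
  envelope; the weak envelope is continuous, so rings close and fill
  to whole cells while sensitivity stays governed by the strong
  threshold.

The raw area trace finally passes a 3-frame temporal median
(configurable; 1 disables): cells whose blurred ring grazes the
threshold flicker in and out frame to frame, and the median removes
that flicker without biasing 30-min-resolution kinetics.

## Normalization and quality control

Viability is normalized twice: first to the same well's value at the
baseline frame (frame W, defined as 100%), absorbing the well-to-well
spread in how many cells land in the photographed field; then to the
mean of the vehicle-control wells at the same time point (at least 2,
reference layout 10), absorbing drug-independent death or growth.  By
construction the mean of the normalized controls is exactly 100% at
every time point.  A well whose baseline area is zero is flagged
`static_start` and excluded from control means.

A sample's run is **valid** when mean control viability at 60 h is
≥ 60% of baseline, **invalid** below 50%, and **conditional** in
between — accepted only if, among drugs showing any effect, at least
half order their endpoint viability by dose (Spearman ρ ≤ −0.8 across
the five doses).  Time lookups use the nearest acquired frame at or
before the requested hour.  Positive-control wells (a reference cell
line at the top dose) are scored like treatment wells but only feed a
per-drug "active" annotation (endpoint viability below 50% of
control); they never enter dose–response fits.

## Dose–response analytics

Replicate traces (duplicates by default; median for n ≥ 3 behind a
flag) are averaged into a dose × time surface.  **LD50** at the
evaluation time (default: last frame) is the dose where viability
crosses 50%, interpolated linearly in log10-dose — apt for the 1:5
geometric dilution; a parametric logistic fit over 5 points × 2
replicates is deliberately avoided.  If viability exceeds 50% at the
top dose the LD50 is right-censored and reported as 2× the top dose;
below 50% already at the lowest dose it reports the lowest dose with a
below-range flag (no extrapolation); non-monotone surfaces use the
lowest-dose crossing and carry a flag.  **AUC** integrates
viability/100 over time per dose (trapezoid, normalized by the
integrated span so 1 = no effect, 0 = instant kill) and averages
across doses; an integrate-over-dose-mean variant sits behind a flag.

Library triage splits a minimal-active-concentration table three ways:
inactive at every dose in every sample; active only above the
pre-selection threshold (0.5 µM); active at or below it in ≥ 1 sample.

Cross-sample analytics: Pearson (optionally Spearman) correlation of
per-sample response vectors between same-class drugs; xenograft event
times as the first linear-interpolated crossing of 25% human CD45 in
peripheral blood or earlier morbidity; leukemia growth-delay ratio as
median treated event-free survival over median control; censored
LD50s enter rank correlations at their 2× Cmax encoding.

## The synthetic time-lapse generator

The simulator renders what the detector must detect or resist, with
per-cell ground truth.  Defaults are the study conditions of the
reduced geometry: 256 × 256 px, 48 frames at 30 min (a 24-h run), 100
blasts of radius 8 px (the reduced-field equivalent of 4,000
cells/well), 2 stromal cells (preserving the assay's 100 MSC : 4,000
blast ratio), background 30, cell brightness +70, ring depth −18,
Gaussian sensor noise σ = 2, a ±7.5% illumination gradient fixed to
the camera, and optional stage drift.  Full scale (2,048 × 1,536, 192
frames) runs behind a flag.

* **Membrane jitter**: each live blast redraws, every frame, a
  low-order Fourier perturbation of its ring radius (modes 0, 2, 3;
  amplitude scale 1 px).  Real membrane-motion amplitudes at 5× are
  not published; this default is a synthetic choice making live/dead
  separation non-trivial but solvable.  Positions stay fixed — the
  collagen pins cells — so live signal is wobble, not translation.
* **Death** is instantaneous freezing of shape and position at an
  exponentially distributed time whose rate follows a Hill function of
  dose: `h(c) = h_max · c^s / (c^s + c50^s)`, s = 2.  `h_max`
  defaults to 2·ln2/24 h⁻¹ so that 24 h at the half-effect
  concentration kills half the cells, making `c50` the 24-h LD50 by
  construction — the recovery experiments' ground truth.
* **Stroma** are larger elongated bright blobs on a random walk
  (step σ = 2 px/frame) that drag any blast within contact range by
  0.3× their step, logging each displacement.  At default density
  this inflates an all-dead well's apparent viability by only a few
  percent; at 20× density the inflation is of order the live signal
  itself — the dead-cell-moving artifact the assay controls by using
  few stromal cells.
* **Independent substreams**: live cells, pre-dead cells, stroma,
  death draws and sensor noise each consume their own seeded stream,
  so perturbing one ingredient (inserting dead cells, sweeping stroma
  density) leaves every other realization untouched.  Pre-dead cells
  are placed at least 3 cell radii from live ones so insertion does
  not physically occlude live rings.  Scenes requesting > 60% of the
  frame as cell footprint are rejected.

### What the simulator does and does not establish

Passing tests show the pipeline separates wobbling from frozen discs
under noise, drift, illumination gradients and stromal traffic, and
recovers a known dose–response.  The stylized optics omit
phase-contrast halos, focus drift, debris, apoptotic morphology
(blebbing), cell lysis and brightness decay after death, and stromal
spreading/shape change — so green tests bound algorithmic behavior,
not performance on real microscopes.

## Numerical choices and degenerate inputs

Evaluation times snap to the nearest acquired frame at or before the
request.  A constant or content-free frame contributes a (0, 0) shift
with a warning flag; registration flags annotate QC but never void a
well.  Control means below 1e-9 leave normalized values undefined
(NaN, flagged).  The dead-cell-insertion robustness property is judged
on the mean absolute change over the trace: per-frame deltas between
two almost-identical scenes retain marginal-detection flicker that the
trace-level comparison correctly averages out.  Ties in rank
correlations are handled by the underlying statistics library; the
triage partition is exhaustive and disjoint by construction.

## Problem sizes used in tests

The suite exercises the reduced geometry throughout: single wells of
256 × 256 × 48 for detector properties; recovery plates of 4 vehicle
controls + 5 doses (1:5 series, 8–5,000 nM, true c50 = 20 nM) per
seed, 10 seeds; density sweeps at 25–200 cells with radius 6 px; and
small 96–128 px scenes for unit-level checks.  The acceptance script
re-runs three recovery plates plus the bookkeeping arithmetic.

## Known limitations

Whole-well area is blind to single-cell fates: it cannot distinguish
quiescent-but-alive from slowly dying cells, and sub-3-h death is
invisible because the baseline itself is defined at 3 h.  Stromal
motion contaminates the signal in proportion to stromal density; the
area cap (`max_object_area_px`, off by default) is a blunt instrument
against it.  LD50 is undefined beyond the tested range except via the
censoring convention.  The registration model is translation-only.
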