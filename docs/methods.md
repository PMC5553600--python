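# Methods

This note documents the models, conventions and numerical choices
behind `lgequant`: what the synthetic phantoms emulate, how each
quantification method is defined, how the reproducibility statistics
are computed, and what the design left open.

## The phantom

Each phantom is a stack of 8–12 short-axis slices on a regular grid
(default 128×128×10 at 1.5×1.5 mm in-plane, 8 mm slice coverage). Per
slice the LV is an annulus between an endocardial and an epicardial
radius; the defaults taper from 25/35 mm at the base to 7/27 mm at the
apex so the apical-most slice has a nearly obliterated cavity and acts
as the apical cap of the 17-segment model. Tissue classes and their
plateau intensities (arbitrary units):

| class | default intensity | notes |
|---|---|---|
| remote myocardium | 100 | optional textural SD on top |
| infarct core | 1000 | angular sector, endocardium outward to a transmural depth |
| grey zone | 550 (midway) | shell at the infarct rim, see below |
| no-reflow | 50 | dark innermost fraction of the core |
| blood pool | 800 | inside the endocardium |
| air | 0 | background |

The infarct occupies an angular sector of the annulus from the
endocardium out to `transmural_fraction` of the wall. The grey zone is
the set of infarct voxels within `grey_zone_width × (transmural wall
thickness)` of remote myocardium, i.e. a spatial shell of intermediate
plateau intensity standing in for partial-volume and peri-infarct
effects; no sub-voxel partial-volume model is attempted. The optional
no-reflow core is the innermost `no_reflow_fraction` of core voxels by
radius, carved out of the core, so core / grey / no-reflow are disjoint
subsets of the myocardium by construction.

Ground-truth infarct size counts core and no-reflow at weight 1 and
grey at weight 0.5 (the MANUAL-ISI convention); all masks are exposed
so alternative conventions can be recomputed. Mass uses a myocardial
density of 1.05 g/mL and a voxel depth of slice thickness + gap
(contiguous coverage), so gapped acquisitions do not under-count.

Noise is Rician by default (magnitude of a complex signal with iid
Gaussian channels, SD `noise_sd` per channel), with a plain Gaussian
option for analytic tests. At remote SNR above ~3 the Rician mean is
within a few percent of the Gaussian one, which the tests assert.

### Simulated readers

Human tracing error is smooth, not white: a reader's endocardial and
epicardial contours are the true circles displaced radially by a
periodic correlated Gaussian field over contour angle (white noise
circularly convolved with a Gaussian kernel of angular width
`contour_error_correlation_length`, default 40°, renormalized so the
marginal SD equals `contour_error_sd` exactly), plus an optional signed
bias. Perturbations that invert the endo/epi nesting are resampled a
bounded number of times. The default 1 mm radial SD is a calibration
choice — no quantitative characterization of inter-reader contour error
was available to set it — and it is the single most influential knob in
the simulation: it alone produces nonzero between-reader CV for the
fully automated border algorithms.

Grey-zone ambiguity is modelled separately (see MANUAL below), and
`correction_completeness` is the per-region probability that a reader
actually performs each available manual correction in the AUTO-UC arms.

### Cohorts

A cohort draws per-patient true infarct sizes from normal(20, 10) %LV
truncated to [2, 60] by resampling (an acute-STEMI-like spread; the
truncation keeps sizes physical and shrinks the realized SD to ≈9.2).
Infarct geometry is solved per patient so the rasterized ground truth
lands near the drawn target: with transmurality drawn from U(0.5, 0.8),
the angular extent follows from the annulus band fraction
(r_f²−r_en²)/(r_ep²−r_en²). All randomness derives from one master seed
through a per-(patient, reader, stage) seed-sequence tree, so cohorts
are bit-reproducible and stages independently replayable.

## Quantification methods

All methods share the same final bookkeeping: a per-voxel weight map in
[0, 1] over the reader's rasterized myocardium mask;
%LV = 100·Σweights/Σmask. A voxel is myocardium iff its center is
covered by the epicardial polygon and not strictly inside the
endocardial one (pixel-center rule, boundary ties resolved
inside-epi/outside-endo).

**Weighted threshold ("Segment-style").** Remote myocardium is located
with no user input as the 60° angular sector (5° steps, pooled across
slices) of minimal mean intensity. The detection threshold is
t = μ_r + k·σ_r (k = 1.8 default); the fully infarcted plateau F is the
mean of supra-threshold intensities at or above their 0.75 quantile
(robust to hot pixels); weights ramp linearly from 0 at t to 1 at F.
The exact weighting of the commercial implementation is unpublished;
this linear ramp is this package's surrogate honoring the principle of
summing weighted rather than dichotomous volumes. Degenerate contrast
(F ≤ t) falls back to weight 1 with a warning; no supra-threshold voxel
yields a zero map with a "no infarct detected" status.

**FWHM.** The maximum M is the 99th percentile of myocardial intensity
per volume (configurable to the global max; per-volume rather than
per-slice is a declared choice). Classification is dichotomous above
M/2 (`half_max`) or μ_r + (M−μ_r)/2 (`half_range`, additionally
offset-invariant). A credibility guard returns a zero map when M/2
fails to clear μ_r + 2σ_r, standing in for the visual pre-screen that
kept infarct-free controls out of quantification.

**User corrections (AUTO-UC).** The simulated reader adds the true
no-reflow region at weight 1 and removes any connected supra-threshold
blob that overlaps true infarcted tissue by less than 10%, each with
probability `correction_completeness`; regions are traced to polygons
and applied through the same rasterizer as everything else.

**MANUAL and MANUAL-ISI.** In simulated-reader mode the classification
starts from ground truth: the perceived outer boundary of the grey
shell is shifted by a per-reader Gaussian offset (SD
`grey_boundary_jitter_sd`, default 0.5 mm, measured as distance from
the bright core), modelling disagreement about where grey tissue ends.
MANUAL includes the bright core plus a per-reader uniform fraction
u ~ U(0.5, 1) of the perceived shell volume (innermost voxels first):
readers instructed to include "any hyperenhanced tissue" include at
least as much grey as the fixed 50% rule but differ in how far out they
go. MANUAL-ISI applies weight 0.5 to the reader's full perceived shell.
This construction guarantees MANUAL ≥ MANUAL-ISI for every reader,
reproduces the mean-size gap between the two, and concentrates the
extra between-reader variance in MANUAL — the mechanism by which an
explicit intermediate-signal rule improves reproducibility. A
threshold-mode classifier (bright ≥ 0.7·R, grey in [0.35, 0.7)·R with R
the maximal myocardial intensity — surrogates for the preset
window/level) exists for data without ground truth. With zero jitter
the simulated-reader classification equals ground truth exactly.

**VISUAL and VISUAL-ISI.** Slices split into basal/mid/apical thirds by
count (remainders to basal, then mid); 6×60° sectors for basal and mid
rings, 4×90° for apical, measured from the RV insertion angle; the
apical-most slice becomes segment 17 when its cavity is below 10% of
its epicardial area. Extent scores use the 5-point scale (0; 1–25;
26–50; 51–75; 76–100%) and VISUAL size is Σ midpoints(13/38/63/88%)/17.
The segment SI score bins the mean intensity of hyperenhanced tissue
(no-reflow counted at reference level) against the brighter of the
brightest hyperenhanced voxel and the blood pool, on the same quartile
edges; VISUAL-ISI multiplies each extent midpoint by an SI weight that
reuses the midpoint fractions (0.13/0.38/0.63/0.88) — the published
scale prints the extent midpoints but not the SI weight mapping, so
this reuse is a declared, configurable convention.

**SNR/CNR.** Plain ratios: mean tissue intensity over the air-ROI SD
(n−1), CNR = SNR_infarct − SNR_remote; no Rician floor correction.
Phantom ROIs are centroid-anchored disks (infarct core, remote
myocardium, image corner).

## Statistics

Reproducibility follows the core-laboratory recipe: per patient, the
mean of all pairwise absolute between-reader differences; CV is
100 × SD(those per-patient means, n−1) / mean method measurement.
ICC is the two-way random-effects, absolute-agreement, single-rater
form ICC(2,1), computed from mean squares in-package with the F-based
CI (Satterthwaite denominator df); the test suite cross-checks it
against an enumerated mean-squares oracle (to 1e-10) and against
pingouin. Variance components use the one-way moment estimators
σ_e² = MS_within, σ_T² = max(0, (MS_between − MS_within)/k). Sample
size is n = ceil(2σ²(z_{α/2}+z_β)²/δ²) per arm with α = 0.05 two-sided,
β = 0.2 and δ ∈ {3, 5, 7} %LV by default; σ combines both components
in quadrature (√(σ_T²+σ_e²)), switchable to σ_T alone since reports in
this area are not always explicit about the choice.

## Problem sizes and tolerances

The mechanism experiments in the test suite use 30-patient, 3-reader
cohorts at 96×96×8 (five master seeds for the ISI comparisons, three
contour-error levels {0.3, 1.0, 2.5} mm for the monotonicity check);
the full-battery bookkeeping check runs at 128×128×10. These sizes give
stable CV orderings at desk scale. Noiseless recovery of true infarct
size by both automated algorithms is asserted to 1 %LV, the
rasterization tolerance at 1 mm pixels; VISUAL is only asserted to one
midpoint-bin width (12 %LV) of truth, its intrinsic quantization.

## What the phantoms do not show

The phantom is a clean annulus: no papillary muscles or trabeculations
(the exclusion rule for detached structures is honored trivially), no
breathing/arrhythmia artifacts, no surface-coil shading, no
inversion-time misadjustment, and a single compact infarct per patient.
Passing tests therefore demonstrate the internal consistency of the
methods and the stated variability mechanisms — not performance on
clinical images, where endocardial border detection and artifact
handling are harder than anything simulated here. The grey-zone
ambiguity model (one scalar boundary offset plus an inclusion fraction
per reader) is deliberately low-dimensional; real reader disagreement
is spatially structured. Sample sizes computed from simulated σ values
track the simulation's between-patient spread, not any particular
trial population.
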