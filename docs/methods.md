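# Methods

This note documents the models, conventions and design decisions behind
`germaquant`, in the order the pipeline applies them.

## Coordinates and units

All geometry is carried out in physical micrometres, axis order (z, y, x),
right-handed, origin at the centre of the stack's corner voxel. Confocal
stacks of germaria are strongly anisotropic (default voxel 0.43 µm in z vs
0.14 µm in xy), so all distances, sphere-membership tests and detector
scales convert through the voxel size; nothing is computed in index space.

## The phantom generator

The phantom emulates the acquisition the pipeline targets: a germarium
imaged in full Z with scan-time laser-power correction.

**Geometry.** Nucleus centres are rejection-sampled on an ellipsoidal
shell (default semi-axes 10 × 10 × 20 µm, thickness 2.5 µm — the follicle
epithelium wrapped around the germline) with a hard minimum separation of
0.8 × the mean nuclear diameter (2.5 µm, s.d. 0.15 µm). The AP axis is
the long (x) axis, ap = 0 at the anterior tip. An optional rigid rotation
(recorded in the truth) mis-orients the sample the way a mounted germarium
is mis-oriented.

**Expression.** Each channel has an AP profile: the nuclear stain is
flat; Eya follows a steep logistic rise centred near the region 2a/2b
boundary (22 µm on the default 40 µm shell); Cas a gradual linear rise;
the Wnt reporter a one-phase decay (plateau 10, y0 100, K 0.08 µm⁻¹ in
arbitrary counts). Per-cell expression is the profile mean times one
lognormal draw (default σ 0.15–0.2): fluorescence intensities are positive
and right-skewed, and a multiplicative model keeps them so. Clone cells
multiply selected channels by a configurable effect; the clone-marker
channel is rendered only in clone cells ("positive" polarity, MARCM-style
marker gain) or only in non-clone cells ("negative", ubi-marker loss).

**Imaging.** Nuclei render as spherical Gaussian blobs (σ = diameter/4)
whose amplitude equals the cell's expression, so the mean intensity inside
the nucleus sphere is proportional to expression — real Hoechst-stained
nuclei are lumpier, but spheres are sufficient to exercise the
coarse/core two-pass logic, which is what the phantom exists for. Depth
attenuation multiplies signal by e^(−a·z) (default a = 0.01 µm⁻¹); in the
default `pre_corrected` mode the scan-time laser ramp divides it back out
exactly, which is the state of laser-corrected data, while residual
attenuation mode feeds the depth-bias QC. Then isotropic Gaussian PSF
(σ 0.2 µm), constant background (5 counts), Poisson shot noise and
Gaussian read noise (SNR 10 means nuclear peak / Gaussian σ = 10). All
draws come from one seeded generator: identical parameters and seed give
bitwise-identical stacks.

**What the phantom does not model** — germline cyst morphology, muscle
sheath, photobleaching, non-rigid tissue curvature, realistic chromatin
texture. Passing tests therefore demonstrate the pipeline's correctness
on tissue-scale geometry and intensity statistics, not robustness to every
real-microscope artefact.

## Detection

The coarse pass runs a scale-normalised Laplacian-of-Gaussian (σ =
diameter/4 per axis, in µm) over the nuclear-stain channel, takes local
maxima above `sensitivity` × the strongest response, and accepts them
greedily by descending response with a minimum separation of 0.7 ×
diameter; ties break by raw intensity then (z, y, x). Centres are refined
to the intensity centroid inside the spot sphere, giving sub-voxel
localization (~0.05 µm on phantoms). The default sensitivity 0.25 was
calibrated on the 50-cell SNR-10 phantom to reach recall ≥ 0.95 and is a
config parameter, not a constant. The core pass masks the channel to each
coarse sphere and places one core spot (default 1.75 µm; 2.0 µm supported)
at the masked centroid — it can neither add spots nor leave the coarse
sphere. Manual curation is represented as add/remove coordinate lists in
the config.

Outlier nuclei are flagged, not removed: cells whose core-sphere stain
mean or coefficient of variation has a robust z-score (median/MAD,
consistency factor 1.4826) above 3.5 — the quantitative signature of
condensed or diffuse stain in dividing/dying/damaged cells. Below 5 cells
the statistics are meaningless and no flag is set.

## Geometry

The mid-sagittal plane is the least-squares plane of the detected centres
(normal = smallest principal component; sign toward +z). The canonical
rotation maps that normal to +z and the in-plane component of a
user-supplied anterior hint to −x ("anterior to the left"); the hint
stands in for the experimenter's visual identification of the anterior
tip. The AP coordinate is the x position with the anterior-most cell at
0 — a straight-line coordinate, adequate for the near-straight germarium;
arc-length along a curved midline is out of scope. Region labels map
half-open AP intervals `[b_i, b_{i+1})` onto the ordered labels R1, R2a,
R2b_A, R2b_P, R3_S1, S2plus; boundaries are user landmarks (or taken from
phantom truth), since the anatomical cues (germline cyst shape) are not
modelled.

## Quantification and normalization

Raw per-cell intensity is the mean over voxels whose centres fall in the
core sphere; edge-clipped spheres are measured over the in-bounds subset
and flagged. Background is the mean over 8–12 core-sized spots placed in
signal-free tissue across exactly two Z planes (auto-sampled away from all
detected nuclei, or manual centres), subtracted with a floor at zero.
The depth-bias QC splits control cells into z terciles and passes iff the
maximum pairwise band-mean ratio is ≤ 1.15 (configurable) — the residual
error of scan-time laser correction.

Normalization modes:

* **max** — divide by the per-sample maximum over non-excluded cells;
  values in [0, 1], maximum exactly 1; scale- and permutation-invariant.
* **control** — divide by the mean of internal-control cells (≥ 3
  required); a clone cell's value reads directly as fold change.
* **decay** — fit `y(x) = P + (y0 − P)e^(−Kx)` to internal-control cells
  (trust-region least squares, bounds K ≥ 0, P ≥ 0; initialised at
  P̂ = min y, ŷ0 = max y, K̂ from a log-linear fit of y − P̂; up to 3
  restarts at inflated K̂) and divide each cell by the prediction at its
  AP position. R² is 1 − SS_res/SS_tot about the mean; constant data is
  reported as an exact constant fit with R² = 0 by convention. Divisors
  below 5% of the fitted y0 are clamped to that floor and the cell
  flagged, preventing blow-ups where the curve approaches zero
  posteriorly. The decay is fitted to background-subtracted intensities.

The fold-change CI (`fold_change_ci`) is a delta-method interval on the
log ratio of means using a small-sample t quantile — both the clone and
the control mean carry sampling error, and ignoring the denominator's
share visibly under-covers.

## Fate classification and statistics

A cell is "high" for a marker when its normalized value is ≥ the
threshold (boundary counts as high); the four Eya/Cas combinations give
precursor (low/low), main body (high/low), polar/stalk (low/high) and
double positive. Thresholds are user-set or data-driven: the density
minimum between the two largest modes of a Gaussian KDE per marker, with a
0.5 fallback (and warning) for unimodal data, taken at a stage where the
markers are fully resolved.

Group comparisons follow a variance-gated tree with gate α = test α = 0.05
by default (both configurable): two groups — F-test, then unpaired
two-tailed *t* (similar variance) or two-tailed Mann–Whitney; ≥ 3 groups —
Brown–Forsythe (median-centred Levene), then one-way ANOVA with Tukey HSD
or Kruskal–Wallis with Dunn's z-tests on pooled tie-corrected ranks,
Bonferroni-adjusted over all pairs (the classical Dunn correction; other
software may adjust differently, so the correction is recorded in the
result). Compact letters come from insert-and-absorb on the significant
pairs: groups sharing a letter are not distinguishable. Degenerate
inputs are defined, not errors: identical constant groups give p = 1.

Fisher's exact test uses the two-sided probability-mass definition (sum of
all fixed-margin tables no more probable than the observed one); a zero
margin returns p = 1. Tukey box summaries use linearly interpolated
quartiles and whiskers at the most extreme data within 1.5 IQR.

## Problem sizes in the test suite

Tests exercise 50-cell phantoms (≈ 60 × 190 × 320 voxels × 5 channels),
chosen as a realistically dense follicle epithelium that keeps a full
pipeline run at a few seconds; clone-effect power and CI coverage use 50
simulated mosaic samples of 75 cells at the table level (the renderer is
validated separately, and the statistic under test consumes tables); the
gated-test calibration uses 1000 null datasets of 20 cells per group; the
Fisher implementation is compared against exhaustive hypergeometric
enumeration for every 2×2 table with total ≤ 60.

## Known limitations

Detection assumes roughly spherical, similar-sized nuclei; touching nuclei
closer than 0.7 × diameter merge. The sagittal-plane fit needs the cell
cloud to be thinner in one axis than the others; on nearly spherical
clouds the plane is ill-defined (though the AP axis, being the long axis,
survives this). Clone assignment thresholds the clone-marker channel at
the midpoint of its 10–90 percentile spread, which assumes a clearly
bimodal marker. The decay-normalization floor makes posterior cells'
fold changes conservative rather than explosive.
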