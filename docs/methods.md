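# Methods

`tapetrace` decodes time-resolved transcriptional activity from images of
intracellular protein-tape fibers, and ships a forward simulator so every
stage can be validated by parameter recovery. This note records the models,
the numerical choices, and what the synthetic benchmarks do and do not
demonstrate.

## The recording principle

A tape fiber nucleates inside a cell at time `t0` and elongates
symmetrically from its center, so position along each half-fiber encodes
deposition time. Three monomer classes write the record:

* **structural** — constitutive, forms the backbone (constant deposition);
* **timestamp** — carries a self-labeling tag; switching the applied dye at
  a known wall-clock time writes a detectable color transition at the
  arclength grown by then. In vivo, an induction (Tet-On) pulse plays the
  same role through its rise onset, decay onset, and the fiber terminus;
* **signal** — expressed from an activity-dependent promoter; its local
  density reports promoter activity at deposition time.

Decoding maps the *fraction of fiber length* `f` (distance from the split
point divided by the half-fiber length) to real time through a monotone
transfer function fitted to the timestamp anchors plus the terminus, which
always corresponds to the fixation time.

## Forward model

**Growth.** `s(t) = a (t − t0)^b` per half-fiber, with `b = 1` (linear) by
default and `b < 1` for the decelerating regime that quadratic/power
transfer functions describe. The inverse `t(s)` is closed-form, so
ground-truth arclength↔time maps are exact.

**Deposition.** The structural channel is constant; signal channels carry
the activity waveform evaluated at deposition time. Promoter pulses are
bi-exponential (`tau_rise`, `tau_decay`; peak-normalized to `amplitude`);
the induction pulse is a saturating rise followed by an exponential decay.
Dye channels are piecewise-constant by the switch schedule, smoothed along
arclength with a centered Gaussian (`σ_s = 0.3 µm`) emulating finite
labeling kinetics; because the smoothing is symmetric, the dye-equality
point of consecutive dyes sits exactly at the switch arclength.

**Geometry.** Fiber centerlines are bounded-curvature random walks (turn
per step ≤ `max_curvature · ds`), grown in both directions from the soma
center and steered back at full curvature near the confinement radius.
Scene defaults: soma radius 10 µm, final half-length 8 µm (lognormal, 20%
CV, clipped to the confinement span), max curvature 0.25 µm⁻¹, nucleation
at day 0.4 ± 0.2, fixation at day 10.5, one dye switch at day 5.5, and a
promoter pulse at day 7.

**Imaging.** Fibers are rasterized as constant-radius tubes (0.3 µm) with
per-arclength intensity, somata as solid spheres on a Nissl channel, then
blurred with an anisotropic Gaussian PSF (σ = 0.2/0.2/0.6 µm laterally/
axially; stacks are acquired at a 0.4 µm Z-step, 0.25 µm pixels). Noise is
Poisson shot noise at a configurable photon scale plus Gaussian read
noise; a helper calibrates the photon scale to a target peak SNR. The
noise-free intermediate is deterministic; all randomness hangs off one
seed.

What the simulator deliberately omits: optics-accurate (Gibson–Lanni)
PSFs, photobleaching, fiber–fiber steric interaction, lateral fiber
thickening, and background autofluorescence structure. Passing recovery
tests therefore demonstrates correctness of the computational chain under
idealized-but-noisy confocal conditions, not robustness to every real
tissue artifact.

## Readout pipeline

**Segmentation.** Fibers: local Gaussian-mean adaptive threshold (4 µm
block), a robust MAD noise estimate with a contrast floor (5% of the
99.9th-percentile foreground, so near-noise-free volumes do not admit the
PSF halo), 3³ closing, small-object removal, and optional marker-based
watershed. Somata: Otsu threshold, hole filling, and a distance-transform
watershed that splits touching cells. Distance transforms use physical
spacing throughout.

**Skeletonization.** Two routes: PCA + smoothing cubic spline (fitted
through the central 80% of voxels by projection quantile, evaluated there,
then linearly extended to the full mask extent), and morphological
thinning + longest geodesic path + smoothing spline (the fallback when the
PC1 explained variance of the voxel cloud is below 0.8 and projection
ordering would fold). Both resample to 1,000 equidistant points.

**Terminus recovery.** The centerline is recentered onto the intensity
ridge (perpendicular-disc centroid, two iterations, ≤0.3 µm per step) and
smoothed with a 0.8 µm odd-reflection moving average — without this, shot
noise wiggle inflates arclength by up to ~25% at SNR 5. Each end is then
adjusted along its tangent by up to 20% of the geodesic length, stopping
at the first of: a genuine local minimum of the 0.5 µm moving-averaged
structural profile (below 60% of the local contrast and followed by a
rebound — a trough between structures, not a noise dip); the sustained
crossing below 40% of the end-local fiber contrast (the mid-edge of a
PSF-blurred tube end; kept below 50% because the anisotropic PSF dims
axially running segments); or a significant rise above the fiber level
(the ray entered another or a folded-back structure). Ends already below
the crossing level retract, and a retracted end is re-extended along its
corrected tangent. Featureless profiles run to the cap and are flagged.

**Profiles.** Trilinear interpolation at each centerline point (the
high-throughput route), or cylindrical averaging: discs perpendicular to
the local tangent at 0.06 µm intervals, sampled on mid-area radii of
equal-area annuli (3 rings, 36 points) — midpoint quadrature in r² keeps
disc means of smooth fields accurate to well under 1%.

**Quality control.** A fiber survives iff geodesic length ≥ 8 µm, skeleton
PC1 explained variance ≥ 0.8, and the majority of its centerline points
fall inside one segmented soma.

**Split search.** Exhaustive at profile resolution inside a window about
the geometric center (full span 20% of length for cultured cells, 10% — a
5% radius — in vivo), maximizing the Pearson correlation between the two
halves resampled to a common 500-point fractional grid on the reference
(timestamp) channel; ties break toward the center.

**Baseline normalization.** Per channel, `(I − B)/B` with `B` the mean
within a 5%-of-length radius around the split — the oldest material.

**Timestamp detection.** Dye switches: a two-segment ("hinge")
least-squares changepoint on the smoothed (2% of length) *later-minus-
earlier* dye difference — differencing cancels the shared geometric gain
that the anisotropic PSF imprints on single channels — refined to the
dye-equality zero crossing inside the fitted rise when one exists (exact
for symmetric incorporation; bias −0.001 d, SD 0.036 d on the noise-free
ensemble), with the rise-segment midpoint as the sharp-step fallback.
Induction pulses: the rise onset is the hinge breakpoint fitted only up to
half-rise (so the concave approach does not drag it late), and the decay
onset is the last sample within 2% of the plateau maximum (expression
falls the moment induction stops). Undetectable events raise a detection
failure and exclude the fiber, with the reason logged.

**Transfer functions.** Linear for two anchors (one switch + terminus),
quadratic (default), power `t = α f^β + γ` (β solved by bracketing on the
third anchor, or nonlinear least squares for more), or a monotone PCHIP
spline for three-plus; piecewise-linear directly connecting anchors is the
in vivo convention and extrapolates with terminal slopes. Any fit found
non-monotone on [first anchor, 1] falls back to piecewise-linear and is
flagged. Anchor interpolation self-corrects smooth arclength distortions:
between anchors, only the *relative* mapping error matters.

**Waveform analytics.** Peaks are local maxima above `2 × pre-reference
SD`, sustained ≥ 3 samples, with optional minimum peak distance and
pre-smoothing to stop noise splitting one peak; FWHM by linear
interpolation of half-maximum crossings; onset is the last upward
threshold crossing before the peak. The line-length statistic is the sum
of absolute successive differences in a window. Time-lagged Pearson
correlation uses the overlapping window at each lag; the two-mode
coupled/decoupled classification is 2-means on the lag-correlation
vectors with deterministic farthest-pair initialization, the cluster with
higher mean correlation near zero lag labeled "coupled", and a fixed
`r ≥ 0.5` threshold rule for degenerate (all-identical) cohorts. Fibers
are assigned to the soma holding the strict majority of centerline points;
the longest fiber represents each cell.

## Accuracy budget (synthetic, SNR 5)

Measured on the default scenes: dye-switch anchors are located to
±0.04 d; the terminus is the weakest anchor (±0.2–0.3 d equivalent)
because the tube-end edge is one PSF wide and orientation-dependent.
Recovered single-pulse peak times have ~0.12 d median absolute error
(~1% of the recording span). Narrow pulses are limited by the *temporal
PSF* — axial blur divided by elongation rate, ~0.3–0.75 d at defaults —
so resolution studies use pulses with FWHM ≥ 1.4 d and bracket events
with a two-switch schedule. The two warped halves of one fiber correlate
at a median r > 0.97 per channel; the worst-oriented fibers reach ~0.92
on narrow-pulse channels, a direct image of the terminus error.

## Problem sizes

Benchmarks use 128³-voxel volumes (51 × 32 × 32 µm) holding two cells
each: 20 rendered fibers for the single-pulse study, 20 for the two-pulse
study (5 seeds), 10 noise-free records for the induction-pulse anchors,
and 5 × 40 cells for the coupling cohort. These sizes give stable rates
while a full study completes in about a minute on one CPU.

## Known limitations

* Heavily folded fibers (length ≫ confinement diameter) defeat both
  skeleton routes and contaminate profiles through the PSF; the explained-
  variance QC filter is the intended guard, and borderline survivors carry
  the largest decoding errors.
* The terminus anchor inherits the full PSF edge ambiguity; transfer fits
  are least accurate in the last day before fixation.
* In vivo, the induction-pulse rise/decay anchors are *one-sided* onsets:
  PSF blur shifts their apparent feet early by up to one temporal-PSF
  (~0.5–1 d at slow growth), so the whole recovered axis can sit late by
  a comparable amount. Dye-switch anchors do not suffer this because the
  dye-equality crossing is symmetric under blur.
* The split search assumes one nucleation point; branched or multi-seed
  assemblies are out of scope (branched skeletons are flagged).
* `segment_somata` assumes blob-like cell bodies; elongated or hollow
  somata would need different markers.
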