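# Methods

## Scope and data model

The package analyzes calibrated AFM height maps (`HeightMap`: a
rectangular grid of heights in nm with a square pixel size in nm/px).
Coordinates are continuous nm with the origin at the centre of the
top-left pixel, x rightward along columns, y downward along rows — the
raster order of AFM scan files. Heights are measured above the substrate
plane at 0 nm. Three interchange formats are supported (plain-text
matrix with a three-line header, x/y/z triplets forming a complete
regular grid, and single-channel 32-bit float TIFF carrying the pixel
size as JSON in the image description); round trips preserve heights to
32-bit precision and the pixel size exactly.

## Synthetic topographs

Because the analyses are meant for before/after scan pairs of
nanosurgically manipulated molecules, the simulator produces exactly
that, with exact geometric ground truth attached.

**Layouts.** M-complexes are spherical caps: a blob is parameterized by
its sphere radius R and apex height h ≤ 2R, giving the closed forms used
throughout the tests — cap volume V = πh²(3R − h)/3 and support radius
√(R² − (R − h)²). Titin filaments are circular-segment ridges along
polylines: the cross-section is the top of a circle of tube radius r_t
protruding h above the plane, so a sub-nm apparent height needs no
separate width parameter. Overlapping features combine by per-pixel
maximum (surfaces occlude; they do not add).

**Default conditions.** Dried preparations: blob peak 4.4 nm, filament
peak 0.3 nm, tube radius 3 nm; hydrated blobs are emulated by setting the
peak to ~16.6 nm. M-complex arrays place blobs along a line with gaps
drawn N(29.37, 7.12²) nm; the oriented ("meniscus-stretched") mode lays
filaments parallel with perpendicular offsets drawn N(20.14, 7.12²) nm.
Default pixel size is 2 nm/px on a 1000×1000 nm field — enough to
resolve a 7 nm tip and 20–30 nm spacings within a ~500² pixel budget —
and the default tip radius is 7 nm. Scan sizes and pixel densities are
package choices (reasonable for this kind of imaging), not measured
facts.

**Manipulation.** A drag across a filament replaces the targeted segment
(half-extent r₀ around the contact point) with a two-strand loop whose
transverse displacement samples the tip-shifted thin-plate profile on
|r| ∈ (d, r₀] at a configurable arc step (default 1 nm); the excluded
|r| ≤ d region reproduces the gap between the strands at the loop
vertex, and strand apex height drops to 0.2 nm (partial unfolding thins
the strand from its native 0.3 nm). The untargeted remainder of the
layout is conserved exactly. A drag through a blob scales it
isotropically so its cap volume grows by exactly the prescribed
increment (volume scales with the cube of the isotropic factor), and can
append a pulled-out strand whose per-vertex axial height follows a
prescribed sigmoid. Drag distances are restricted to the instrument's
working range, 10–300 nm, with 0 allowed as an explicit no-op.

**Tip convolution.** The recorded image is the grayscale (max-plus)
dilation of the surface by a spherical probe; the probe is a sphere
because only a tip radius is specified (a paraboloid would complicate
the oracle for no benefit). The kernel is the apex-relative sphere
height sampled on the pixel grid; the fast path is
`scipy.ndimage.grey_dilation` with that structure and footprint, and the
test suite holds it to *exact* equality with an independent brute-force
max-plus oracle on random maps. Borders use nearest-pixel padding.
Dilation is extensive (output ≥ input) and monotone in tip radius.

**Scan artifacts.** Per scan: a per-line linear background (offset and
cross-width ramp each drawn N(0, tilt_sd²)), i.i.d. Gaussian roughness
(default 0.05 nm, typical of dry tapping-mode baselines), then a single
multiplicative gain — the simplest model consistent with a ratio-based
inter-scan correction. All draws are seeded; reruns are bit-identical.

## Topography analysis

**Flattening** fits a polynomial (order 0–2) per scan line to background
pixels only — a supplied foreground mask is subtracted but never fitted —
and subtracts it from the whole line; order 0 subtracts the per-line
background median. The operation is idempotent for a fixed mask. A line
with fewer than order + 1 background pixels is an error naming the row.
The pipeline applies a two-pass scheme: flatten without a mask, threshold
to find foreground, then re-flatten the raw image excluding it.

**Thresholding** defaults to median + k·1.4826·MAD (robust SD) with
k = 3, which tolerates tilt residue and does not depend on the foreground
fraction; a fixed nm level is available as an override. The threshold
rule is a package default, documented here because no single convention
is universal. An empty mask warns rather than fails (blank scans are
legal).

**Volumes.** Feature volume is Σ(heights over mask) × pixel_size².
Negative post-flattening heights are kept with their sign; clipping would
bias volumes upward. Volume is additive over disjoint masks and scales as
gain¹ and pixel_size².

**Inter-scan bias correction.** With an unmanipulated reference object
present in both scans, bias_ratio = V_ref(before)/V_ref(after) and
ΔV = bias_ratio·V_target(after) − V_target(before). The ratio is applied
to the after-scan volume (the direction is a convention; the
gain-cancellation test pins the implemented one): any gain common to the
whole after-scan cancels exactly. Masks are drawn per scan; no
registration is attempted.

**Profiles** are sampled along polylines at pixel_size steps by bilinear
interpolation (the AFM-software convention); an averaging width > 0
means each sample is the mean over a perpendicular segment of that
width.

## Filament metrics

Traces are operator inputs (CSV polylines); `trace_ridge` offers a
steepest-ascent centerline as a convenience, but no measurement depends
on it. Contour length is the Euclidean polyline length. Peak spacings
use `scipy.signal.find_peaks` with prominence ≥ 0.3 nm and separation
≥ 10 nm by default (suited to M-complex arrays; both overridable);
fewer than two peaks yields n = 0, not an error. Strain is
(L₁ + L₂)/L₀ with L₀ measured along the pre-manipulation contour between
the loop's rejoin points and L₁, L₂ along each strand to the apex gap
edge — contour lengths, not chords, which is an interpretation choice.

**Necking.** At each axial station along a strand trace, a perpendicular
cross-section is fitted with a rectangular function h(x) = H for
|x − c| ≤ W/2, else 0, by exhaustive least squares: c over the sampling
grid, W over the half-pixel grid, H closed-form (the mean of the
enclosed samples) for each (c, W). Exhaustive search (a few hundred
candidates per section, evaluated with prefix sums) avoids the local
minima a gradient method would find on a discontinuous model. A section
whose maximum does not exceed the height floor is degenerate and reports
H = 0, W = 0 with a flag; stations whose section leaves the map are
skipped with a warning. Fitted width grows monotonically with tip radius
(wider probe, wider apparent strand), which the suite asserts.

## Parametric models

All fitters follow the `Model(data).fit() → Results` convention; results
carry estimates, asymptotic standard errors (from the final Jacobian),
SSR, and r² = 1 − SS_res/SS_tot. The nonlinear engine is
`scipy.optimize.least_squares` (trust-region reflective) with documented
initial guesses and 5 multiplicative log-normal (20%) jittered restarts;
the best convergent solution wins, ties broken by smallest parameter
norm; no convergent start raises an error carrying the attempt
diagnostics.

**Thin-plate loop.** u(r) = k·ln(r₀/(|r| − d)), the sign-symmetric form
(both printed branches collapse under |r|); d = 0 recovers the original
model, so the models are nested. ν, P_x and E are never unlumped from k
(they are not separately identifiable from loop shapes). Initial
guesses: r₀ from the data half-span, d from the 7 nm nominal tip radius
(capped below min |r|), k from max u/ln(r₀/d + 1). When d is free, the
nested d = 0 optimum is also computed and adopted if the optimizer's
free-d solution lands above it, so SSR(tip-shifted) ≤ SSR(original)
holds unconditionally. The model applies to loops nearly symmetric about
the drag axis; the caller asserts symmetry.

**Sigmoidal height decay.** h(x) = B + (T − B)/(1 + (x/x₁/₂)^S) with
S > 0 decays from the maximal plateau T at the M-complex centre to the
minimal plateau B far out, and satisfies h(x₁/₂) = B + (T − B)/2
exactly. The direction matters: with the ratio written the other way up
the same family rises with distance instead, contradicting both the
physical decay and the minimal/maximal reading of B and T, so the
decaying orientation is implemented (the two differ only by the sign of
S). Initial guesses: T and B from the first/last quartile of samples,
x₁/₂ from the mid-height crossing, S = 2.

**Distribution fits** operate on fixed-origin histograms (origin 0,
Freedman–Diaconis bin width unless specified) because fitting
"statistical frequency" requires a binning convention. The exponential
fit normalizes counts by the first occupied bin so the zero-intercept
form f = e^(−c·l) anchors at 1 there, and fits c by least squares on the
bin centres; the closed-form MLE rate 1/mean is always reported
alongside (the two agree within ~20% for truly exponential data at
n ≥ 200, and the histogram estimator carries noticeably more sampling
spread than the MLE at that size). Both `ExponentialModel` and
`GaussianModel` also accept precomputed histograms (`from_histogram`)
for noiseless oracle checks. The linear fit is ordinary least squares
through statsmodels, reporting a confidence interval for the intercept
so "intercept = 0" (one titin-associated unit per molecule) is a
testable claim.

**Fold volumes.** Hydrated/dry volume ratios from apparent heights read
as diameters: (h_wet/h_dry)³ for a sphere (M-complex), (h_wet/h_dry)²
for a fixed-length cylinder (filament). Equal heights give exactly 1;
the ratio is strictly increasing in the hydrated height.

## Pipeline

`run_experiment(RunConfig)` executes simulate → flatten → segment →
metrics from a single pydantic-validated config; every default is echoed
into the report (no silent defaults), outputs are written as text
matrices plus a ground-truth JSON, and identical config + seed yields
byte-identical summaries. Stage failures abort with the stage name;
partial outputs are preserved. Two bundled configs exercise the headline
recoveries:

* `volume_demo_config` — two 16.6 nm M-complexes, one expanded by
  3300 nm³, gains (1.0, 1.2), 0.05 nm roughness, tip radius **0**. Tip
  dilation is off here by design: measured AFM volumes are apparent
  (tip-convolved) volumes, and for a cap blob grown by 3300 nm³ a 7 nm
  tip inflates the apparent increment by roughly 30%, so a recovery
  check against the geometric increment is only meaningful without
  dilation. The package deliberately performs no tip deconvolution
  (out of scope), so its volumes on real images are apparent volumes —
  directly comparable between scans, not absolute.
* `spacing_demo_config` — a 21-blob M-complex array with gaps
  N(29.37, 7.12²), imaged **with** the 7 nm tip and noise; the
  profile-based spacing mean must land within 3 SEM of the generating
  mean.

`reproduce_headline_numbers` (CLI: `titinafm reproduce`) tabulates the
analytically forced quantities — sphere-equivalent diameter
(6·3300/π)^(1/3) = 18.5 nm of the mean volume increment; fold volumes
(16.64/4.39)³ ≈ 54.5 and (5.89/0.97)² ≈ 36.9; height ratios ≈ 3.8 and
≈ 6.1 — plus the seeded recovery checks, each with its tolerance and
pass/fail.

## What the synthetic data does and does not show

The simulator reproduces the features the analyses are sensitive to:
cap/ridge geometry with exact volumes, tip broadening, line tilt,
additive roughness, and inter-scan gain. It does not emulate feedback
artifacts (parachuting, overshoot), thermal drift or creep between
scans, double-tip imaging, adhesion-induced height compression, or the
molecular mechanics of manipulation (outcomes are imposed
geometrically). Passing recovery tests therefore demonstrates that the
estimators are correct and unbiased under the modelled corruptions — not
that they are robust to every artifact real scans can contain. Real-use
caveats: volumes are apparent volumes; drift between scans must be small
enough that re-masking per scan suffices, since no registration is
performed.

## Problem sizes and numerical choices

Test and demo images are 150–500 px on a side (fields of 300–1000 nm at
1–2 nm/px), chosen so cap-volume discretization error stays below 1% at
pixel sizes ≤ radius/10 (asserted in the suite) while the whole test
suite and the demo pipelines each run in well under a minute. Replicate
recovery checks use 100 seeded replicates at the study sample sizes
n = 14, 20, 28 and require the fitted mean within 3 SEM of the
generating mean in ≥ 90 of them. Degenerate inputs have defined
behaviour throughout: empty masks warn (thresholding) or fail (volume
integration), monotone profiles yield n = 0 spacings, flat cross-
sections report degenerate top-hat fits, zero-distance manipulations are
no-ops, and domain violations of u(r) (inside the apex gap or beyond
r₀ + d) raise errors naming the domain.
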