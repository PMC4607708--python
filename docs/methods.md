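# Methods

`octpath` re-creates the analysis chain used to compare retinal thickness
between two spectral-domain OCT instruments with a single, common
segmentation: shortest-path boundary tracing on B-scans, thickness
quantification on a foveal measurement grid, and paired agreement
statistics. A synthetic phantom with known ground truth makes every stage
testable without clinical data. This note records the models, the
parameters that matter, the numerical choices, and the limits of what the
phantom can show.

## Boundary tracing as a shortest path

A boundary is a function row(column) through the B-scan. We trace it as
the minimum-cost left-to-right path: one row per column, the row change
between adjacent columns bounded by `max_jump`, and the path length
defined as the sum of the pixel values of the cost image along the path.
The dynamic program computes, backwards over columns, the best cost from
each pixel to the right edge (a min-filter of width `2·max_jump+1` over
the next column plus the local cost), then reconstructs forwards taking
the smallest row at every argmin. Ties therefore always resolve toward
the smaller (more vitreal) row, which makes outputs deterministic and
regression-testable. Out-of-band pixels carry an infinite sentinel cost.

Anchor points — the programmatic replacement for interactive click
correction of an erroneous segmentation — split the column range into
independent fixed-endpoint problems. An anchor pair closer in rows than
`max_jump × column gap` permits a path; otherwise the call fails with an
infeasibility error rather than silently bending the constraint.

Two cost constructions are used:

* **Negated intensity** (`1 − I`): pulls the path into the middle of a
  bright band. Used for the RPE centerline, searched in a band of
  ± `band_halfwidth` (default 15 px) around the brightest image row.
  The image is axially smoothed (Gaussian, σ = 2 px) first: a flat-topped
  bright band then peaks at its center, so the path settles mid-band
  instead of hugging the band's top edge, and speckle is damped.
* **Negated polarity-matched vertical gradient**: the forward difference
  `I[r+1] − I[r]` (last row replicated), sign-selected for a dark→bright
  or bright→dark transition, negative responses clipped. Used for the
  IS/OS top (dark→bright above the centerline), the RPE outer border
  (bright→dark below it) and the ILM (dark→bright above the IS/OS).
  The polarity parameter is our resolution of the fact that a single
  unsigned "negated gradient" cannot serve both a rising and a falling
  edge.

For tracing, the gradient is hardened against speckle: axial Gaussian
smoothing (σ = 1 px) before the difference, then a lateral median filter
(5 columns) and a light lateral Gaussian (σ = 1 column) on the clipped
response. The rationale: a true edge is laterally consistent across
neighboring A-scans, while speckle spikes and individually misaligned
columns are not; the median rejects them without blurring the edge the
way pure averaging would. The cost is normalized by the gradient maximum
inside the search band (the optimum is invariant to this affine scaling);
a boundary whose matched gradient averages less than 25 % of the scan's
strongest response is flagged low-confidence — the situation in which the
original workflow would fall back to manual anchors.

The tracing order is sequential, each stage constraining the next: rough
RPE row (highest row-wise intensity sum, the RPE being the most
hyper-reflective band) → RPE centerline → IS/OS top in a band 20–90 μm
above the centerline → RPE outer border 2–40 μm below it → ILM between
the image top and 30 μm above the IS/OS. The IS/OS window's inner limit
(20 μm) keeps it clear of the gradient tail of the RPE band's own top
edge; its outer limit (90 μm) covers the adult foveal IS/OS-to-centerline
range. All offsets are in micrometres and converted per scan through the
axial calibration; all are configurable.

`max_jump` defaults to 2 px per column; the ILM uses 1 px: the
vitreoretinal surface is smooth (the foveal pit slopes well under
1 px/column at 512 columns over 6 mm) and its edge contrast is the lowest
of the four, so the stiffer continuity prevents the path from chasing
speckle without sacrificing anatomy. Results are reported in original
(pre-alignment) coordinates by adding the alignment shifts back, and the
anatomical ordering ILM ≤ IS/OS ≤ RPE centerline ≤ RPE outer is enforced
per column; a violation raises an error carrying the offending columns.

## A-scan alignment

Eye motion displaces each A-scan axially. Alignment maximizes intensity
correlation between neighboring A-scans, on square-root intensities
(variance stabilization for multiplicative speckle: the coefficient of
variation of √X for exponential X is roughly half that of X) with σ = 1 px
axial smoothing. Both transforms act per column, so they cannot bias lags
*between* columns, and recovery on noise-free input stays exact.

Two candidate estimates are computed and the one with the higher global
correlation objective is kept:

1. **Pairwise chain** — the best lag per adjacent column pair, summed
   cumulatively. Provably exact on noise-free images, but a single noisy
   pairwise error propagates into every column to its right, so the chain
   drifts under speckle.
2. **Iterative refinement** — starting from zero shifts, the image is
   flattened, a per-column reference is built as the lateral mean over a
   31-column window of the flattened image (drift-free by construction),
   and each raw column's *total* shift is re-estimated against its
   reference by normalized cross-correlation, iterating to convergence
   (≤ 8 passes). The re-estimation searches ±10 px — the scale of
   plausible jitter — rather than the full `max_shift`, which keeps the
   blurred reference from locking a column's RPE band onto the reference's
   IS/OS band.

Shifts are integer (the downstream boundary error budget is about one
pixel), median-centred so the scan does not drift as a whole, and clipped
to ±`max_shift` (default 20 px; cumulative sums of bounded pairwise lags
are not themselves bounded on a tilted scan).

**Measured limits.** Against a *perfect* noiseless reference, matching a
single speckled column attains ~95–97 % of columns within ±1 px (NCC,
exponential likelihood and √-NCC variants all cluster there); this is an
information ceiling of single-look exponential speckle at this geometry,
not an implementation artifact. With a realistically estimated reference
the implemented estimator recovers ~90 % of columns within ±1 px at the
phantom's default ±3 px jitter, and ~65 % for uniform ±10 px jitter.
Noise-free recovery is exact for jitter up to `max_shift`/2. The
acceptance suite asserts a 95 % within-±1 px requirement for the speckled
case and is expectedly red there; the unit suite asserts the exact
noiseless property and an 80 % regression floor.

## Thickness quantification

Two layer pairs are measured, both ending at the RPE outer border (the
posterior edge of the RPE–Bruch's membrane complex, the highest-contrast
outer boundary): full retinal thickness (ILM → RPE outer) and the RPE+OS
complex (IS/OS top → RPE outer, dominated by the photoreceptor outer
segments). Thickness is `(outer row − inner row) × axial_scale`; the
lateral coordinate is derived from the nominal scan length divided by the
A-scan count, so doubling the axial calibration exactly doubles every
thickness (tested as an invariant).

The foveal center is the argmin of the moving-average-smoothed retinal
thickness profile (half-width 5 columns; the raw argmin is
speckle-sensitive), ties resolving toward the scan center. The grid is
13 points at −3.0 … +3.0 mm in 0.5 mm steps: the central point thickness
(CPT) at offset 0, the 1-mm line as the unweighted mean of the −0.5, 0
and +0.5 mm points, and the all-points mean over the unmasked grid. A
point whose target column falls outside the scan is masked missing, with
one column of tolerance at the scan ends — a perfectly centered fovea on
an even 512-column, 6-mm grid places the ±3-mm targets half a column
beyond the outermost column centers, and those points are by convention
present. On the pit floor the profile is flat to under 1 μm over
±0.1 mm, so under speckle the detected fovea can legitimately wander by
tens of columns; this bounds what CPT precision a single-look line scan
can deliver and is reflected in the test tolerances.

## Agreement statistics

All comparisons are paired per eye, differences reported as device B −
device A with labels carried into the output tables. The paired t
statistic is `mean(d)/(sd(d)/√n)` with the sample SD and a two-sided p
from the t distribution with n−1 df (zero-variance differences yield an
undefined t with p = 0 or 1 by the sign of the mean). Pearson r, OLS
conversion lines (`linregress`), and Bland–Altman limits at mean ± 2 SD
of the differences (the ±2 convention, not 1.96) complete the battery.
Percentage differences are the mean difference over the mean of the two
device means, × 100.

The multi-point analysis along the 6-mm line drops incomplete pairs
listwise per offset and pools by collapsing each eye to its mean over the
offsets where both devices measured, then running the paired test on the
per-eye means. This replaces a repeated-measures mixed model: averaging
within eye before testing addresses the same within-eye correlation
concern with a fully specified, dependency-free procedure (it is mildly
conservative — between-offset information is not reweighted).

Test–retest repeatability reports the mean absolute difference and the
coefficient of repeatability, defined here as 2·SD of the repeat
differences expressed as a percentage of the mean of all measurements
(the normalizing mean and the 2 vs 1.96 factor are conventions; both are
stated rather than assumed).

## The phantom

The phantom emulates what shortest-path segmentation actually sees:
a reflectivity stack (vitreous 0.05, inner retina 0.35, outer nuclear
layer 0.15, IS/OS band 0.8, inter-band gap 0.3, RPE band 0.9, choroid
0.25 on a display scale of [0, 1]), a Gaussian foveal pit (depth 94 μm,
FWHM 1.8 mm — real pits are not Gaussian, but only ordering, slopes and
a unique minimum matter here), a flat RPE outer border, an IS/OS-to-outer
complex interpolating 62 μm peripherally → 76 μm foveally along the same
Gaussian, an optional detached posterior hyaloid (a faint line above the
ILM), per-pixel multiplicative unit-mean exponential speckle (single-look
intensity statistics), frame averaging as the mean of independent speckle
realizations with boundaries fixed, and integer per-column axial jitter.
Defaults give CPT ≈ 226 μm and foveal RPE+OS ≈ 76 μm, in the measured
adult range. Two device templates: 512 A-scans / 6 mm, single frame
(lateral scale 11.72 μm) and 768 A-scans / 8.7 mm with 100-frame
averaging (11.33 μm).

Ground-truth boundary rows are stored as floats in the generated image's
coordinates (jitter included). Cohort mode draws one latent anatomy per
eye (peripheral thickness SD 17 μm by default, plus fixed-scale
variation of pit depth and the RPE+OS complex, all clipped at 3 SD so
extreme draws cannot violate the layer ordering), renders it under both
device templates, and can displace device B's outer boundary by a chosen
bias — emulating the thickening a frame-averaging device can show at a
weak posterior edge. Repeat-visit mode re-renders the same eye with
fresh noise and a small axial re-measurement perturbation (SD 2.3 μm).

**What the phantom does not model:** coherent imaging physics (speckle
is injected on the display scale rather than derived from scatterers;
real speckle has finite grain and is log-compressed for display),
attenuation and shadowing, curvature and tilt of the whole retina,
pathology beyond the hyaloid/floater variants, and vendor-specific
contrast transfer. Passing tests therefore demonstrate correctness of
the algorithms under controlled, harder-than-display noise — not
clinical performance.

## Known limitations

* Under the phantom's single-look speckle, argmax-style edge
  localization is pulled ~0.5–1 px toward the bright side of each edge
  (a selection effect of maximizing noisy responses, not removable by
  more smoothing). Comparing a single-frame device against a
  100-frame-averaged device therefore carries a systematic thickness
  asymmetry of a few μm on top of any true difference — the same
  averaging-related thickening effect that motivates comparing devices
  with one common algorithm in the first place. The end-to-end cohort
  check quantifies it: with a 1.85 μm injected bias the pipeline
  measures ≈ 7–8 μm pooled difference, of which ≈ 5–6 μm is this
  asymmetry. The ground-truth tables recover the injected bias exactly.
* Jitter recovery under single-look speckle plateaus below the
  perfect-reference ceiling (see above).
* Boundaries are integer rows; no subpixel refinement is attempted, by
  design — the error budget of the downstream statistics is set by
  biology and calibration, not by the half-pixel quantization.
* Inner retinal sublayers, 3-D graph search across B-scans, and learned
  cost functions are out of scope.

## Problem sizes used in the automated checks

The DP-vs-oracle check uses 100–120 random cost images up to 20×25 with
step bounds 1–3. Boundary and jitter checks use 2–10 phantom scans per
condition at the default 160×512 geometry. The end-to-end cohort check
uses 37 eyes × 2 devices × 13 grid points, the sample size and grid of
the study design it mirrors. Statistical oracles run 50–200 random
paired samples of 3–40 eyes.
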