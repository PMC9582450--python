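# Methods

This note documents the models, estimators, and numerical choices
behind `retitort`, and what the synthetic benchmark does and does not
establish about behavior on real fundus images.

## Problem setting

Retinal vascular tortuosity — how much vessels bend per unit length —
is an early quantitative marker of diabetic retinopathy (DR).  The
analysis separates vessels into four classes (main/branch ×
artery/vein), assigns each patient one overall tortuosity value per
class, and compares groups of patients (non-DR vs DR; mild vs moderate
vs severe DR) with one-way ANOVA.  The scientific signal of interest
is that severity effects concentrate in **branch arteries**.

Because the clinical images behind the published tables are not
deposited, the package ships a synthetic fundus generator whose
geometry (hence curvature) is known in closed form.  All quantitative
validation is against that ground truth.

## Synthetic scenes

A scene is a bright background with a linear illumination ramp and
corner vignette, a Gaussian-blob optic disk, and vessel tubes that
attenuate the background multiplicatively with an inverted-Gaussian
cross-section (`sigma = 0.6 x tube radius`).  Multiplicative
attenuation keeps vessels darker than their local background under any
illumination, which is what the local-normalization stage assumes.
Additive Gaussian sensor noise comes last.  Centerline families:

* straight (curvature 0),
* circular arc (curvature `1/R` exactly),
* sinusoid `y = A sin(2 pi t / lambda)`, whose arc-length-weighted
  mean |curvature| is evaluated by dense quadrature (`dt = 0.01 px`)
  and inverted for `A` by bracketed root finding when a target
  curvature is prescribed.

Cohorts draw a per-patient, per-class target curvature from a
truncated normal (curvature is positive) and build 4–8 trunks radiating
from the optic-disk rim, each with one branch splitting off at 35–60°.
Every segment of a class is constructed to have *exactly* the
patient's target mean curvature, so the patient-level truth is the
drawn target itself.  Arteries render at 70% of vein contrast and 80%
of vein caliber; branches at 45–55% of trunk caliber.  These rendering
gaps are what make artery/vein and main/branch learnable; they are
package choices, not published values.

The published tables print tortuosity in an unanchored unit
(`x 1e-4`, physical pixel pitch unstated).  The default cohort adopts
the published *pattern* of group means at one table unit = `1e-3 px^-1`,
which puts synthetic vessels in the curvature range the estimator
resolves at the default 768 px image scale.  Absolute table values are
therefore not comparable to published ones — only differences,
orderings, and significance structure are, which is also all the
acceptance surface uses.

What the generator does **not** emulate: pathology (microaneurysms,
hemorrhages), vessel crossings between arteries and veins, central
reflex stripes, field-of-view borders, and realistic texture.  Passing
benchmarks on these scenes shows the estimators are correct on known
geometry, not that accuracy transfers to clinical data.

## Enhancement and segmentation

Local normalization subtracts the windowed mean and divides by the
windowed SD (default window 65 px, reflect padding), with a
zero-variance guard.  Enhancement evaluates the gamma-normalized
(`sigma^2`-scaled) oriented second derivative `n^T H n` at 12
orientations and scales {1.2, 2.0, 3.2} px after a 1 px pre-smooth;
dark-on-bright polarity is enforced by clamping negative ridge
responses.  The pre-smooth exists because local normalization whitens
sensor noise to unit variance, and an unregularized 1.2 px derivative
scale responds to that noise as strongly as to vessels.

Thresholding is hysteresis with both thresholds anchored at the Otsu
split of the response (strong = 1.2x, weak = 0.6x Otsu).  Area-percentile
thresholds were tried first and rejected: they tie the mask area to the
scene's vessel density, which varied Dice between 0.66 and 0.92 across
fixture densities.  Otsu anchoring holds Dice at 0.88–0.95 on both
sparse and dense scenes, noiseless and at default noise.  A percentile
mode (`q` = kept fraction) remains available.

## Vessel graph

Masks are skeletonized; junction pixels (>= 3 skeleton neighbors) are
removed to split segments; spurs shorter than 10 px are pruned; points
are ordered endpoint-to-endpoint, lightly smoothed (moving average,
endpoints pinned), and given per-point radii from the distance
transform.  Coordinates are 0-based `(row, col)` with pixel centers at
integers.

The main/branch split operationalizes the clinical rule "largest
vessels originating at the optic disk are main".  Region growing
starts from segments intersecting the disk; at each junction the main
label passes only to the largest-caliber neighbor at the *far* end of
the parent (entry/far endpoints are tracked explicitly), and only if
its mean radius is at least `caliber_quantile` (default 0.8) of the
parent's.  Ties break to the lower segment id.  The far-endpoint
bookkeeping matters: with plain adjacency the label leaks back to the
sibling of a continuation at the same junction, which cost ~35% of
label accuracy in early testing.  The optic-disk location is taken
from ground truth for synthetic scenes and must be supplied explicitly
for external images.

## Artery/vein classification

Ten intensity statistics per segment (mean, SD, median, min, max — of
pixels inside circles of 1.5 local radii around centerline points, and
of intensities sampled along the centerline) feed a logistic
regression on z-scored features with an L2 ridge of 1e-6 (for
separable data).  Classification is per segment; the label propagates
to all its points.  Training labels on synthetic cohorts come from the
ground-truth geometry via nearest-centerline matching, standing in for
the expert annotations used with clinical data.  Features use the raw
(un-normalized) image: normalization would equalize exactly the
artery/vein depth contrast the classifier needs.

## Tortuosity

The image (locally normalized, inverted so vessels are positive) is
lifted to an orientation score `U(x, theta)` over `theta in [0, pi)`
(unsigned orientations; 16 bins) by convolving with cake wavelets:
Fourier-domain filters with a raised-cosine angular wedge (aperture
`2 pi / n_theta`) centered on the orientation normal and a log-Gabor
radial band (center 0.08 cycles/px, 2 octaves), zero at DC.

At each centerline point the local vessel is modelled as a
constant-curvature arc; its lift is the exponential curve of the
roto-translation group through `(point, theta*)`.  The curvature
estimate maximizes the mean of `U` along that lifted trace over a
window (default 31 px).  Numerical details that matter:

* **Curvature search.**  Coarse grid of 41 values over
  `[-0.1, 0.1] px^-1`, then a 17-point fine grid spanning one coarse
  step around each point's optimum, then one parabolic step.
  Effective resolution ~1e-4 px^-1; a fixed single grid at the coarse
  step cannot resolve the 1/120 px^-1 test radius.
* **Ridge snapping.**  The elongated wavelets displace the response
  ridge of a curved vessel toward the center of curvature (~0.5 px at
  R = 80).  Fitting through the geometric centerline therefore
  overshoots curvature by 20–30%.  Each point is first re-centered on
  the response ridge along the vessel normal (parabolic peak over
  +-2 px); recovery on rings is then within +-2% for R in [50, 120].
* **Window length.**  At 21 px the objective is not selective below
  ~0.01 px^-1 (per-point scatter ~50%); 31 px restores selectivity
  down to ~0.008 px^-1.  Sinusoidal vessels need `lambda/4` above the
  window or local curvature averages out; fixtures respect this, and
  the scaled-down end-to-end cohorts accept the resulting attenuation
  because only significance structure is evaluated there.
  `window_px="auto"` scales the window with vessel caliber (12.4
  radii, clipped to [21, 63] px), which is what makes tau covariant
  under whole-scene rescaling; the fixed default is kept for
  within-scene analyses.
* **End trimming.**  Points within half a window of a segment end have
  one-sided vessel support and bias curvature low; they are flagged
  unreliable (confidence 0) unless the segment is shorter than 1.5
  windows.
* **Theta.**  The per-point orientation comes from the score argmax
  with parabolic refinement (a centerline-tangent mode exists for
  diagnostics).

Per class, tau = `sum(c_i |kappa_i|) / sum(c_i)` pooled over all
points of all vessels of the class (pooling before averaging; the
alternative per-vessel-first average is not used).  Confidence `c_i`
is the positive part of the maximal path integral.  A class with no
confident point is flagged missing, never zero-filled.  Tables
multiply by 1e4.

The independent oracle is a smoothing-spline curvature
(`|x'y'' - y'x''| / (x'^2+y'^2)^{3/2}` on arc length), accurate to 2%
on closed forms.  The orientation-score estimator agrees with the
oracle's unweighted mean within ~10% on noiseless mixed-geometry
scenes; the residual gap is confidence weighting (which favors
straighter, better-resolved stretches) plus window averaging on
variable-curvature vessels.

## Cohort statistics

One-way ANOVA by the standard between/within decomposition (delegated
to `scipy.stats.f_oneway`; an independent textbook implementation
serves as the test oracle, matching to 1e-10).  Sample SDs use the
n-1 denominator.  Two comparisons per vessel class: non-DR vs pooled
DR, and V1/V2/V3.  Significance at p < 0.05, no covariate adjustment,
no multiple-testing correction, per-class listwise exclusion of
missing values — matching the published analysis design.  A fully
degenerate input (zero between- and within-group variance) leaves F
undefined and flagged rather than zero-filled.

The published F statistics themselves are not reproducible from the
published means/SDs/group sizes (the standard decomposition gives,
e.g., F ~ 2.15 where 4.746 is printed), so the statistical acceptance
rests on properties instead: oracle equivalence, type-I error
calibration (0.05 +- 0.02 over 2000 null replicates), and Monte-Carlo
power > 80% at the published branch-artery severity effect sizes.

## Problem sizes

Benchmarks run at desk scale by design: rings at R in {50, 80, 120},
property fixtures of 300–470 px, cohort scenes of 256 px with 8–100
patients, and the end-to-end signature experiment at 60 patients x 10
seeds (the published cohort is 495 patients; power at the injected
effect sizes is near 1 at n = 60, so additional patients only add run
time).  The `default_cohort_spec` reproduces the published group sizes
(122/200/139/34) at 768 px for users who want the full-scale
configuration.

## Known limitations

* Absolute tortuosity values are in px^-1 under package-chosen
  rendering scales; only relative structure maps to the published
  tables.
* The estimator's validated curvature band at the default window is
  roughly 0.005–0.05 px^-1; outside it, use `window_px="auto"` or a
  custom window.
* Vessel crossings are not disambiguated (no artery-over-vein
  topology); crossing-free synthetic scenes sidestep this.
* The A/V classifier is intensity-only and per-segment; no graph
  propagation.
* Optic-disk detection is out of scope; external images need the disk
  supplied.
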