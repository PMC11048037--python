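# Methods

## Scope and model chain

`dazzlesim` models laser dazzle as a three-stage chain: (1) beam
propagation to the cornea, (2) intraocular scattering that converts the
corneal irradiance into a veiling luminance, and (3) a contrast-
threshold detection criterion that decides whether a target survives
the veil.  Derived quantities (dazzle angle, maximum dazzle exposure,
nominal ocular dazzle and hazard distances) are inversions of that
chain.  A foveated-sensor simulator, a spot-image pipeline and a
grey-AHP grading layer sit around the physics.

## Glare physics

**Veiling luminance.**  `L_v = S1·L_b^T1 · g(θ,A,p) · 683·V(λ)·E`, with
`g` the CIE general disability-glare kernel, `V` the CIE 1924 photopic
efficiency (tabulated at 5 nm, linearly interpolated, support
380–780 nm), and `E` the corneal irradiance converted from the mW/cm²
interface unit to W/m².  The `S1·L_b^T1` factor is an empirical
ambient-adaptation calibration (S1 = 0.9147, T1 = 0.1775).  The
photometric conversion term is required for dimensional consistency
(cd/m² out of lm/m² in) and follows the L_v = g·E structure of the CIE
model; it is part of this package's formulation of the veil.

**Threshold contrast.**  `C_thr = Ω(L_b, a)·AF(A)` with
`Ω = 2.6(√Φ/(60a) + √L)²/L_b`.  The luminance-dependent calibration
functions √Φ(L_b) and √L(L_b) are genuinely open design choices; the
shipped defaults are the Adrian visibility-model forms with their
photopic (L_b ≥ 0.6 cd/m²), mesopic and scotopic branches.  Both
functions are pluggable through `GlareCalibration` for users with their
own threshold data.  The target subtense `a` is stored in degrees and
converted to arcminutes (60a) inside Ω.  The age factor uses the
quadratic branch `(A−19)²/2160 + 0.99` up to and including age 64 and
`(A−56.6)²/116.3 + 1.43` above it (the two branches overlap ambiguously
at 64 in the source formulation; ≤ 64 was fixed here); ages outside
[19, 75] are clamped with a logged warning.

**Masking criterion and inversions.**  A target is masked when
`C_orig·L_b/(L_b + L_v) < C_thr` — the standard veiling-glare contrast
reduction.  The threshold is evaluated at the ambient adaptation level
`L_b` only (not `L_b + L_v`), which keeps `C_thr` independent of the
exposure and makes the criterion a monotone function of the veil.  The
dazzle angle solver bisects θ on [0.01°, 90°] to 1e-4°; the strictly
decreasing veil guarantees a unique root.  When even θ = 90° satisfies
the criterion the solver returns the bracket bound with a warning
(physically: the veil overwhelms the whole field).  MDE is the
closed-form inversion `E(θ) = L_b(C_orig/C_thr − 1)/(S1·L_b^T1·g·683·V)`;
scenes with `C_thr ≥ C_orig` (target invisible even unlit) raise a
degenerate-scene error.

**Beam and safety quantities.**  The far field uses a circular top-hat
of diameter `d0 + φL` (exit diameter `d0` defaults to 0).  The MPE
implements only the visible-band CW aversion-response case
`18·t^0.75/t` W/m² with t configurable (default 0.25 s); other regimes
raise with a pointer to the governing standard.  The safety gate alarms
when irradiance strictly exceeds `w·MPE`, `w ∈ [0.3, 0.8]`, default 0.5.

## Foveated sensor

The detector is a disc of concentric-ring pixels: foveal rings with
constant 14 µm radial pitch and a per-ring pixel schedule, peripheral
rings with 520 pixels each and radial extents growing geometrically to
fill the 5113 µm photosensitive radius.  The published reference gives
ring and pixel totals (50 + 88 rings, 6306 + 45,760 pixels) but not the
per-ring foveal schedule; the default assigns ring k a count
proportional to its circumference, `round(6306·(2k−1)/50²)`, corrected
by largest remainder so the schedule sums exactly to 6306.  The printed
R (max/min pixel size ratio, 7.07) and Q (detector/minimum pixel size,
731) values are stored as reference metadata only: the measure behind R
is not defined in the source, and the layout reports its own emergent
values (R ≈ 8.4 under the max-of-radial-and-arc-extent measure,
Q = 730.4) without enforcing the printed ones.

Pixels respond logarithmically, `r = offset + gain·log1p(min(v, sat))`,
invertible below saturation to 1e-9.  Sampling applies the pixel model
to the mean luminance over each footprint, estimated by 4× grid
oversampling (analytic polar integration was rejected as needless
complexity at desk scale); reconstruction paints each output cell with
its containing pixel's decoded value.

## Spot pipeline

Extraction binarizes with Otsu's threshold (parameter-free and
reproducible; a fixed threshold is available), traces edges with a
from-scratch Canny (Gaussian smoothing σ = 1.4, Sobel gradients,
4-sector non-maximum suppression, hysteresis at 0.1/0.3 of the maximum
gradient; all exposed), and reports the mask centroid and
equivalent-area radius `sqrt(area/π)` — the radius definition chosen
for irregular spots.

Compensation finds the largest inscribed ellipse (distance-transform
and centroid seeds × 15° orientation grid, binary-search axis growth,
local centre polish; a local maximum, not certified global), then
replenishes intensity deficits: an angular-median radial profile —
robust to defects spanning under half the circumference — is rendered
and the image raised to it (elementwise max) over the ellipse and any
cells flagged as defects (below half the profile).  Gamma enhancement
`s = gain·r^γ` (default γ = 0.8) preserves Gaussian shape exactly
(σ → σ/√γ), so the subsequent least-squares elliptical-Gaussian fit is
unbiased by it.  The fit runs twice: a first pass pins the centre, a
second pass excludes detected defect cells; a soft-L1 loss guards
against residual coherent outliers.  On 20 seeded synthetic spots with
45° notch defects and 1% noise the pipeline recovers centres to a
median 0.07 cells and radii to a median 0.5%.

The biomimetic halo maps the veiling-luminance profile to image radii
through the retinal scale (291 µm/deg for a 60 D schematic eye) and
composites additively in linear intensity (a screen operator is
available) followed by min–max tone mapping; the source gives no
compositing objective, so the operator is a config enum.

The synthetic generator renders ground-truth Gaussians with optional
sector-notch and rectangular-occlusion defects and seeded additive
noise; defaults (σ = 8 cells, 45° notch, 1% noise) emulate a moderately
corrupted acquisition.  It does not model speckle phase noise, detector
fixed-pattern noise, or saturation — passing recovery tests bound
performance on clean-ish frames, not on heavily speckled real imagery.

## Grey-AHP grading

The hierarchy has four criteria (incident radiation U-A, retinal damage
U-B, imaging characteristics U-C, glare perception U-D) with 5/2/3/5
indicators carrying 1–3 leaf factors each.  Weights come from the
geometric-mean method with Saaty's consistency ratio reported (warning
above 0.1); aggregation is bottom-up weighted averaging, so criterion
scores stay in the convex hull of leaf scores and are monotone in every
leaf.  The expert judgment matrices behind the original grading are not
published: the shipped defaults are neutral all-ones matrices (equal
weights), replaceable through config, and the per-scenario Level column
shipped with the 21-scene fixture is therefore a regression reference,
not a reproduction target.

Grey classification uses trapezoidal whitening over the per-criterion
intervals with a linear crossfade band of 10% of the narrower adjacent
interval at each internal boundary — memberships sum to one everywhere
and split 0.5/0.5 exactly on a boundary.  Scores above the top interval
clamp with a warning.  Criterion memberships combine by (default equal)
criterion weights; ties break toward the more severe level, the
conservative choice for a safety assessment.  Because the source gives
no factor-scoring rubric, measurements map to leaf scores through
documented piecewise-linear defaults (irradiance on a log scale over
1e-3–10 mW/cm² for U-A, irradiance relative to the MPE for U-B, spot
diameter relative to the detector for U-C, occlusion angle over 0–12°
for U-D); an "all covered" saturation flag pins U-C to its top score.

## Scenario runner

The 21-scene fixture spans ambient luminances 0.005–491.52 cd/m²,
incidence angles 0.5–12°, observer ages 30–60 and target contrasts 89%
and 40% (target 0.24 m at 5 m, subtending 2.75°).  Per-scene laser
ranges are not printed for most scenes, so the runner accepts either a
range (irradiance computed from divergence) or a measured irradiance
override; the shipped override table carries the measured values.  The
incidence angle has a 0.5° floor (below it the beam would be obstructed
by the target board) unless constructed explicitly otherwise.  Reports
are deterministic for a fixed seed and byte-stable (sorted keys, %.6g
floats, LF endings).

Dose-effect sweeps evaluate U, the model-driven retinal dazzle diameter
(2·U·291 µm/deg), and MDE over log-spaced ambient grids (0.001–500
cd/m², 60 points) or linear angle grids; crossings against a reference
angle are bracketed on the grid and refined by bisection, with bounded
upper-bracket doubling when the crossing lies beyond the sweep.

## Known limitations

* The analytic dose-effect crossings disagree with measured-image-driven
  ones by orders of magnitude under any monotone threshold calibration:
  with the shipped defaults the U(L_b) = 2.75° crossing sits at
  ~216 cd/m² (89% contrast) and ~537 cd/m² (40%), and the MDE crossing
  at 1.537 mW/cm² at ~8.5°.  A 1.537 mW/cm² corneal irradiance is a
  photometrically enormous glare source (~9300 lm/m²), and the CIE-type
  veil it implies masks moderate-contrast targets across wide angles at
  any plausible ambient level; measured curves reported for comparable
  hardware show far smaller dazzle extents.  The package reports what
  the stated model computes; reconciling the two requires calibration
  data that is not public.
* Only photopic V(λ); no scotopic/mesopic luminous efficiency, no
  pulsed-laser MPE regimes, no retinal-thermal extended-source limits.
* The sensor model excludes transistor-level circuit behaviour, noise
  spectra and readout timing; the spot pipeline does not filter phase
  noise and is not real-time.
* The inscribed-ellipse search is a local optimizer; pathological
  (highly non-convex) masks may yield sub-maximal ellipses.
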