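# Methods

## Scope and model of measurement

`torsometrics` quantifies the externally visible trunk deformity of
adolescent idiopathic scoliosis (AIS) from a triangulated torso surface
mesh, the kind produced by a handheld structured-light scanner.  The
tool is deliberately *semi-automated*: the anatomical judgement — where
the shoulder apex, scapular prominence, PSIS dimples, rib prominence and
neck are — is supplied by the user as regions of interest (ROIs), and
everything downstream of that placement is deterministic geometry.  The
ROI placements are a declarative YAML document rather than an
interactive viewport, so a measurement session is reproducible and
reviewable.

### Coordinate convention

All angles reference world-fixed anatomical planes, never planes fitted
to the mesh: +X is the patient's left, +Y posterior, +Z superior, so the
coronal plane is XZ, the transverse plane XY and the sagittal plane YZ.
Meshes are assumed millimetres and pre-aligned (e.g. by a calibrated
standing-board protocol during scan processing).  No automatic alignment
is attempted; a mis-aligned mesh biases every angle by the mis-alignment,
which is a property of the acquisition protocol, not of this algorithm.
The axis directions themselves are a package convention — surface-scan
exports carry no anatomical axes — and are flagged wherever they matter.

### The five metrics

For a left-right landmark pair with difference `d = left − right`:

* **rotation** `= atan(d_y / d_x)` — deviation of the pair's
  transverse-plane projection from the coronal plane; positive when the
  left landmark is more posterior;
* **tilt** `= atan(d_z / hypot(d_x, d_y))` — elevation of the line out
  of the transverse plane; positive when the left landmark is higher.

These are the unique pair of mutually independent definitions consistent
with reading rotation in a top view and tilt in a back view.  Shoulder,
scapula and hip asymmetry apply these to feature-specific extreme points
inside spherical ROIs: most superior point for shoulders, most posterior
for scapular prominences, most *anterior* for PSIS dimples (the dimple
floor, i.e. the most inward point of the depression).  The directions
are config-overridable; only the PSIS direction is anatomically forced
by the dimple geometry.

**Torso rotation (TR)** scans the rib prominence: two cuboid ROIs
straddle the spine, the mesh is cut by an XY plane every `step` mm
(default 1 mm), the cut is clipped to each box, and the most posterior
point per side forms a line whose rotation is evaluated; TR is the
profile entry of maximum magnitude (signed, ties to the lowest height).
Maximising |angle| rather than the signed angle treats left- and
right-sided humps symmetrically.

**Head-pelvis shift (HPS)** is the X offset of the neck cross-section's
area centroid (shoelace centroid of the largest-area contour — slivers
from scan artefacts are thereby ignored) from the midpoint of the PSIS
dimple line.  Positive = head toward the patient's left.

Angles are reported signed even though magnitudes are what is usually
tabulated clinically; the sign encodes laterality and the magnitude is
derivable.  Choosing the neck plane height is user judgement; no
automatic rule is implemented.

### Numerical choices

* Extreme points are taken over mesh *vertices* inside the ROI, not the
  continuous surface — adequate at scan resolution (vertex spacing a few
  mm), invariant to face ordering, and deterministic.  Ties are broken
  by larger |x|, then smaller z, then larger x, making repeat runs
  bit-identical.
* TR slice extraction uses the exact mesh/plane intersection clipped
  parametrically to each box (not vertex binning), so results are stable
  under mesh decimation; the extreme at a level is a point of the
  surface at exactly that height.
* Cross-section chains are assembled from the raw intersection segments
  with endpoints matched after quantisation to 1e-6 mm.  Open chains
  (cropped scans may be open at top/bottom, and a plane can graze the
  shoulder region) are closed by a chord and flagged, with a warning.
* Rotation is undefined for a landmark pair with |Δx| < 1e-9 mm and tilt
  for a purely vertical pair; these raise rather than return a value.
* `crop_z` keeps whole faces (no triangle clipping); the slab can
  overshoot by one face diameter, which is irrelevant because metric
  queries are ROI-local.
* Smoothing is a single-pass uniform (umbrella) Laplacian with boundary
  vertices pinned.  One pass is the default because repeated smoothing
  erodes exactly the local extrema the metrics read.

## Reliability statistics

Validation of such a tool against human raters uses the two-way
random-effects, absolute-agreement, single-rater intraclass correlation
ICC(A,1) (= ICC(2,1)):

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

with mean squares from the subjects × raters ANOVA without replication.
The 95% CI uses the F-based method with Satterthwaite degrees of
freedom.  Interpretation bands: < 0.5 poor, 0.5–0.75 moderate, 0.75–0.9
good, > 0.9 excellent.  The published band boundaries overlap verbally
at 0.5/0.75/0.9; here 0.5 and 0.75 fall upward (moderate/good) and 0.9
itself is good, the assignment consistent with how values adjacent to
0.9 are conventionally labelled excellent only above it.  Negative ICCs
are reported as computed.  Missing cells are rejected, not imputed —
imputation silently changes the estimand.  `reliability_report` mirrors
the usual study design: per-user intra-rater ICC over sessions, plus an
inter-rater ICC over users' final sessions.

## Synthetic torso generator

Patient scans are not redistributable, so tests use a parametric torso
whose true metric values are known *by construction*, not by re-running
the estimator:

* The trunk is an extruded ellipse (defaults 300 × 200 mm, 500 mm tall)
  whose posterior side carries a flat panel (|x| ≤ 0.73·half-width).
* **Shoulders**: the top rim is wavy, with two Gaussian peaks (baseline
  height 25 mm).  The requested rotation displaces the peaks in ±y by
  Δy/2; the requested tilt raises *one* peak by the full Δz (side chosen
  by sign) — a downward-displaced peak would stop being the superior
  extremum of its ROI, while one-sided raising leaves the defining
  difference Δz, and hence the angle, exact.
* **Scapulae**: Gaussian posterior bumps (σ = 0.133·half-width) with a
  5 mm baseline protrusion so the apex is a unique extreme point even on
  a symmetric back; per-side amplitude and a signed height offset set
  ScR/ScT.
* **PSIS dimples**: negative Gaussians on the panel.  Hip rotation is
  realised by asymmetric floor depths; both dimples are deepened by
  |Δy|/2 over the base depth (minimum 2 mm) so each side remains a
  genuine depression at any requested rotation.
* **Rib hump**: within a vertical window the panel is sheared,
  `y = B + m(z)·x`, where m(z) has a flat plateau (±10 mm) at
  `tan(rib_hump_deg)` and cosine-squared falloff.  Because the sheared
  panel is exactly linear in x, the per-height extreme line's angle is
  `atan(m(z))` independent of the box extents, and any slice level in
  the plateau measures the requested TR exactly — no dependence on step
  phase or ring alignment.
* **Neck**: a cylindrical stub whose centroid is offset laterally by
  `head_shift`; the PSIS midpoint is at x = 0 by symmetry, so the true
  HPS equals `head_shift` exactly.

Every feature centre is snapped onto a grid vertex and that vertex is
then set to the exact analytic landmark position, so ground truth is
exact up to floating point at *any* valid resolution (≥ 36 vertices per
ring; a resolution error is raised when the smallest feature spans fewer
than three vertex spacings).  Optional seeded Gaussian vertex noise
emulates scanner roughness.  `simulate_ratings` adds rater bias and
residual noise around true values, giving a known population ICC
`σ_s² / (σ_s² + σ_b² + σ_e²)` for calibration tests.

Because the generator emits its own recommended ROI set, passing
recovery tests demonstrates the *algorithm* is exact given correct ROI
placement; they say nothing about inter-rater placement variability,
which is precisely what the ICC machinery is for.  The fixture also does
not probe robustness to scan holes, clothing artefacts or mis-alignment.

## Problem sizes

Default test/validation sizes: 144 vertices per ring (≈ 22k vertices,
44k faces) per torso; 20 randomized torsos for recovery runs
(deformity angles ≤ 20°, shifts ≤ 30 mm, noiseless); 1 mm TR step over a
160 mm window; ICC calibration at n = 30 subjects × k = 3 raters with
500 replicates and 100 oracle-comparison matrices.  The full validation
script runs in well under a minute on one CPU.

## Known limitations

* No automatic anatomical landmark detection, ROI placement, or neck
  plane selection — by design, the user supplies anatomy.
* No mesh repair beyond degenerate-face removal; scan stitching, hole
  filling and decimation are upstream concerns.
* The tool assumes a world-aligned mesh; alignment error propagates
  one-to-one into the angles.
* The forward-bend scoliometer analogue (ATR in Adams position) and
  whole-torso symmetry maps are out of scope.
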