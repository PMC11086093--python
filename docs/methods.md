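# Methods

## The estimation model

The estimator treats the body as 12 rigid segments (pelvis, torso, and
femur–tibia–talus–calcaneus–toes per leg) with 23 DOF: six global pelvis
coordinates, a 3-DOF back joint, 3-DOF hips, and single-axis knee, ankle,
subtalar and metatarsophalangeal joints. Three-DOF joints and the global
pelvis rotation use the intrinsic Z–X–Y Euler sequence (flexion–extension,
ab/adduction, axial rotation). Axes are x anterior, y up, z to the
subject's right; the ground plane is y = 0; g = 9.81 m/s².

Anthropometry follows the published Gait2392 default subject (75.1646 kg
reference): segment mass fractions, COM offsets and principal inertia
tensors, with masses and inertias scaled linearly in subject mass and the
geometry held fixed. This makes every force and moment exactly homogeneous
of degree 1 in body mass — a property the tests assert. The oblique
subtalar and MTP axes of the reference model are simplified to the segment
X (inversion–eversion) and Z (flexion) axes; the DOF count and Euler
conventions are unchanged.

### Contact model

Twenty contact points (10 per foot) attach to the calcaneus (2 heel + 4
metatarsal) and toe (4) segments. Horizontal locations come from an
ankle-relative template (the ankle origin is the midpoint of the lateral
and medial malleolus markers). Vertical locations are calibrated from the
static standing trial: each point is placed `vertical_offset` = 30 mm
below its sole reference height, i.e. *below the ground plane while
standing*. That standing penetration is the signal the method reads:
loaded sole regions sit tens of millimetres deep, unloading decompresses
and lifts them. The per-point sole reference heights (heel 0 mm,
metatarsal 16 mm, toe 22 mm) give standing depths of 30/14/8 mm, which
puts the standing COP behind the foot centre — the heel-biased calibration
posture.

Sinkage is gated on position *and* vertical velocity
(`p_crit` = 0 m, `v_crit` = 0.05 m/s): a point moving upward faster than
`v_crit` is treated as unloading regardless of depth. The printed form of
the sinkage definition is negative under contact; we use the non-negative
penetration depth `p_crit − p_y` so the distribution ratios are convex
weights, which the positivity of the vertical GRF requires.

### Frames and conventions

* Contact-point horizontals and the per-foot moments of the distribution
  step are ankle-relative (origin at the grounded ankle projection); the
  COP that follows is therefore ankle-relative as well.
* The VPP is a lab-frame point (whole-body COM + 37.5 mm along the trunk
  frame's +y axis), so the COP is translated back to the lab frame (its
  ankle origin added) before the COP→VPP lever is formed. The reported
  COP is lab-frame; moments are reported about the grounded ankle origin
  by default, or about the lab origin (`moment_origin="lab"`). Both are
  exact re-expressions of the same wrench: the distribution scheme leaves
  no free couple at the COP.
* COP division floor: the COP is undefined when a foot's vertical force is
  below 1% of body weight; such a foot carries no horizontal force and no
  external wrench in inverse dynamics. Without a floor the COP ratio is
  numerically unbounded at touchdown/lift-off.
* Support phase: a foot is "in contact" when its summed sinkage is
  positive; both feet → double support, one → single, none → flight.
  The same vertical distribution applies in every phase; only the
  horizontal channel switches method.

### Kinematics pipeline

Markers are low-pass filtered with a zero-phase Butterworth filter
(forward–backward, half the nominal order per pass, cutoff pre-warped so
the *net* response is −3 dB at the nominal 6 Hz at 100 Hz sampling).
Derivatives are central finite differences (one-sided at the ends; the
second-difference stencil is exact on quadratics).

Segment poses are fitted per frame by orthogonal Procrustes (SVD/Kabsch)
registration of each segment's markers against calibrated locals — a
per-segment substitute for a global inverse-kinematics solve. It is exact
on rigid noise-free data and requires ≥3 non-collinear markers per
segment. The talus carries no markers (as in standard gait marker sets)
and inherits the calcaneus orientation with its origin back-projected
through the subtalar offset. Marker gaps up to 10 frames are linearly
interpolated; longer gaps are an error. Euler extraction warns near gimbal
lock (|X angle| → 90°) and continues.

### Inverse dynamics

Joint torques come from a self-contained recursive Newton–Euler pass over
the segment tree: an outward sweep propagates angular velocity/acceleration
and COM acceleration through each elementary joint rotation (chained
intrinsic Euler rotations handled as successive intermediate frames), an
inward sweep accumulates the transmitted wrench and projects it onto the
instantaneous joint axes. Prismatic DOFs are supported at the root only.
`q̇`/`q̈` are finite differences of the filtered joint coordinates, with no
additional spline smoothing. The six pelvis generalized forces are
reported, not zeroed: they vanish (< 1e−6) on dynamically consistent
input and otherwise quantify the inconsistency between the kinematics and
the estimated wrenches.

## The synthetic-data generator

The generator emulates what a laboratory would record — a 49-marker
whole-body trajectory set at 100 Hz plus ground-truth per-foot wrenches —
for a quiet-standing calibration and level walking at a prescribed speed
(default 1.25 m/s, 1.1 m stride, matching the study population's scale;
subject mass defaults to 55.2 kg).

Construction: the whole-body COM is prescribed in closed form (forward
progression, ±15 mm vertical and ±20 mm lateral oscillation at stride
harmonics, phase-jittered by seed); eleven segments follow plausible rigid
motions (two-link leg IK between pelvis and authored ankle paths, feet
translating through stance/swing) and the torso COM absorbs the residual,
so the mass-weighted COM equals the prescription to machine precision.
Markers are emitted rigidly from the poses, so the Procrustes pipeline
recovers them exactly.

Contact-point vertical trajectories are *authored directly* to emulate
sole deformation (rigid segments cannot deform): each point descends to
its calibrated standing depth, dwells, and lifts off, staggered heel-to-toe
(planting over the first ~11% of stance, lift-off spread over the last
~40%). Load transfer during the ~2×10% double-support windows therefore
happens progressively, point by point, exactly as the velocity gate reads
real lift-off. Ground-truth wrenches are defined by applying the sinkage
distribution law to those authored contacts with the *closed-form*
external force — and, for double-support horizontals, by the VPP
construction itself, which is the only available truth definition for that
channel (a force plate plays that role for real data). Truth and estimate
consequently differ only through what the estimator must measure:
finite-difference COM accelerations in place of the closed form.

What the generator does **not** emulate: soft-tissue artifact, marker
occlusion, foot-segment rotation during roll-over (foot poses translate
without pitching), asymmetric or pathological gait, and the
force-distribution consequences of shoe soles or sloped ground. Passing
round-trip tests therefore demonstrates the internal consistency and
numerical correctness of the pipeline under its own assumptions — not
accuracy on real laboratory data, which is what force-plate validation
provides.

Measurement noise is modelled as independent uniform white noise in
[−a, +a] on every contact-point coordinate (a ∈ {1, 10, 100} mm in the
sensitivity experiment). The sensitivity pipeline passes noisy contact
positions through the same 6 Hz zero-phase measurement filter before
differentiating — contact points are marker-derived measurements, and all
measured kinematics receive that conditioning. Noise corrupts only the
*distribution* of the external force, not its magnitude, which is why
vertical-force accuracy is nearly flat between 1 and 10 mm while the
moment channels (driven by the COP) degrade monotonically.

## Numerical choices

* Filter pre-warp factor `(√2 − 1)^(−1/(2n))` per pass so the two-pass
  −3 dB point lands on the nominal cutoff (verified on a probe sinusoid).
* Kabsch registration uses the SVD determinant correction to exclude
  reflections; a collinear marker cloud raises a degenerate-fit error
  naming the segment.
* Division safety: distribution ratios use a guarded denominator and
  return exact zeros on no-contact frames; the COP floor is 1% of body
  weight; the VPP lever must be positive (`r_VPP_y > p_COP_y`) for every
  loaded foot, else a geometry error.
* Problem sizes: tests and the acceptance script use 4-stride walks
  (~3.5 s, 353 frames at 100 Hz), 1000-instance distribution oracles and
  10 noise realizations per amplitude — sizes at which every quantity is
  stable to well inside its tolerance while the whole suite runs in
  seconds.

## Known limitations

* Single-support horizontal forces are the whole-body horizontal external
  force by definition; double-support horizontal forces follow the VPP
  direction and are not constrained to sum to the external force — the
  residual is a property of the VPP model, not asserted away.
* The per-segment Procrustes fit does not enforce joint constraints, so
  extracted joint angles are not guaranteed tree-consistent on non-rigid
  (real) data; inverse dynamics consumes the tree-consistent coordinates.
* C3D input is not supported; trials must be exported as text TRC.
* Constant ground height (level walking); a sloped plane would require
  reformulating `p_crit`.
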