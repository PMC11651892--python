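# Methods

`kneemech` simulates the mechanics of a cruciate-retaining total knee
replacement through a walking cycle and asks how the intra-operative
tension of the posterior cruciate ligament (PCL) changes joint kinematics,
contact loading and soft-tissue forces.  This note records the model, its
assumptions, the defaults, the numerical choices, and what the synthetic
inputs do and do not represent.

## Model

The knee has twelve generalised coordinates: six tibiofemoral (flexion —
the primary, prescribed coordinate — plus adduction, internal rotation and
the AP/SI/ML translations of the femur relative to the tibia) and six
patellar.  The tibia is the fixed frame: +X anterior, +Y superior,
+Z lateral for a right knee; medial is −Z.  The patellar coordinates are
expressed relative to the *tibia* rather than the femur.  This is a
coordinate-chart choice, not a change of content: it keeps the quadriceps'
flexion moment arm finite (their origins rotate with the femur while the
patella is held by the patellar tendon) so that the extensor mechanism
transmits torque to the tibia exclusively through patellofemoral contact
and the patellar tendon.  Patella-in-femur pose is available as a derived
quantity for reporting.

Three force systems act on the femur and patella:

**Elastic-foundation contact.**  The polyethylene inlay and patellar
button are beds of independent springs of thickness `h`; the cobalt-chrome
femoral component is rigid.  Per foundation face, penetration depth is the
distance from the face centroid, along the inward face normal, to the
first back-face hit on the femoral surface; misses and front-face hits
mean no contact.  Pressure is `p = K d / h` (linear, default) or
`p = −K ln(1 − d/h)` (log), with `K = (1−ν)E/((1+ν)(1−2ν))`.  Defaults
E = 463 MPa, ν = 0.46, h = 6 mm — typical compression-moulded UHMWPE
values; the law and constants are config-exposed because published
elastic-foundation knee models vary in both.  Resultants, the exact
medial/lateral partition, and pressure-weighted centres of pressure (CoP)
follow from the per-face pressures.

**Ligaments.**  Nine bundles (aPCL, pPCL, sMCL, dMCL, LCL, medial and
lateral posterior capsule, MPFL, LPFL, ITB) plus the patellar tendon and a
quadriceps-tendon element, each a set of 1–3 point-to-point fibers with
the quadratic-toe/linear law (transition strain 0.03 for all bundles).
Slack lengths are never free parameters: at the 0°-flexion reference
assembly every fiber is calibrated to its bundle's reference strain,
`L0 = L_ref / (1 + ε_ref)`.  The PCL carries the baseline 2% reference
strain and 180 N/mm of linear stiffness per bundle (split over its
fibers); the tensioning experiment adds −10…+10 percentage points to the
PCL reference strain (absolute −8%…+12%) and recalibrates only the two PCL
bundles at the unchanged reference pose.  Attachment sites are a
literature-guided default table, not subject-specific data; the PCL's
femoral attachments sit 1–2 mm distal to the flexion axis, which sets how
strongly the ligament engages with flexion (chosen so the baseline PCL
carries a modest residual force in late stance, consistent with its role
as a restraint rather than a primary load path, and so the released
ligament is almost unloaded there).  The posterior capsule bundles are
crossed fiber fans (the femoral and tibial spreads run in opposite
senses), which gives the joint its first-order internal/external-rotation
restraint, as the real capsule does.  The quadriceps-tendon element
(25 N/mm) represents the stretched extensor muscle-tendon unit: it keeps
the patella seated when the optimizer assigns the quadriceps zero
activation (swing, late stance) and carries the pre-swing tension a
flexing loaded knee puts on the extensor apparatus.  Straight segments
wrap over virtual cylinders with the tangent–arc–tangent geodesic when a
segment would penetrate one.

**Muscles.**  Twelve knee-spanning rigid-tendon actuators (three vasti,
rectus femoris, three hamstrings plus short biceps head, two gastrocnemius
heads, TFL and popliteus) with literature-typical maximum isometric
forces.  Force is `activation × F_max`; no force–length or force–velocity
scaling — the per-frame force balance, not contraction dynamics, governs
the outcomes of interest.  Hip and ankle are not modelled: proximal
anchors are fixed in the femoral frame and the gastrocnemius' distal
anchor in the tibial frame.  The quadriceps insert on the patella and
share a wrapping cylinder over the anterior femur.

## Implant geometry

All surfaces are parametric stand-ins (the clinical component's CAD is
proprietary): the tibial inlay is a pair of biquadric dishes — sagittal
plus coronal circular sag about the dwell point — whose minimum is the
dwell point *exactly*, for any radius; the low-conformity variant doubles
the sagittal radius (43 → 86 mm) with identical dwell points, so the joint
line is preserved and scenarios are directly comparable.  The femoral
component has a two-radius sagittal profile (40° zone boundary) swept
coronally, plus a grooved trochlea whose sulcus is recessed 3 mm below its
facets.  The distal sagittal radius default is 26 mm, i.e. a sagittal
conformity ratio of about 1.65 against the 43 mm dish — representative of
moderately conforming cruciate-retaining designs, and the property that
gives the standard inlay its anteroposterior restraint.  The patellar
button is a 13 mm spherical dome.  Meshes are regular-grid triangulations
at a 1.5 mm target edge length (dwell points are exact grid samples at
every resolution).

## Equilibrium solver

At each of the 100 frames (integer %GC grid 0–99; toe-off at 63 %GC) the
flexion angle and the external intersegmental wrench are prescribed and
the solver finds the 11 secondary coordinates and muscle activations such
that every secondary generalised force vanishes within 0.5 N
(translations) / 50 N·mm (rotations).  Muscle activations minimise Σa²
subject to the flexion-torque balance and 0 ≤ a ≤ 1; this strictly convex
QP has the exact water-filling solution `a_i = clip(λ c_i/2, 0, 1)` with
the multiplier found from the breakpoint structure — no iteration.

The outer iteration is a scaled Levenberg–Marquardt method on the
11-coordinate residual with a finite-difference Jacobian (forward steps
2×10⁻³ mm / 5×10⁻³ deg), Broyden updates between refreshes, per-coordinate
step caps, and a nested back-tracked correction of the six translational
coordinates after each trial step (contact makes translations orders of
magnitude stiffer than the rotations; re-balancing them before the merit
comparison is what keeps large rotational moves from being rejected).
When the joint iteration stalls, a fallback alternates a translation-only
Newton solve with a Schur-complement step on the five rotations.  The
solver drives residuals to 90% of the reported tolerance so that an
independent re-assembly of the generalised forces at the accepted pose
verifies the full tolerance.  Frames are solved sequentially with linear
extrapolation of the previous two solutions as warm start; frame 0 is
reached by continuation from the reference assembly.  Everything is
deterministic: fixed coordinate ordering, no randomisation anywhere in the
solver.

Inside the solver, contact is evaluated with candidate triangle sets
anchored at a nearby pose and refreshed automatically when the pose
drifts; the public `resolve_contact` path performs the full exact search.
The two agree to machine precision in operation, and the acceptance
certificate uses the exact path.

## Synthetic gait

The generator replaces the upstream marker/GRF/inverse-kinematics
pipeline.  It emits the knee flexion curve and the external intersegmental
wrench at the knee (tibial frame, applied to the femur) for a 70 kg,
1.72 m subject: peak swing flexion 57° at 72 %GC, a two-peaked stance
axial load (~1.05 BW peaks near 15 and 50 %GC, ~0.6 BW valley) built from
Gaussian bumps with heel-strike and toe-off tapers, sagittal knee moments
demanding quadriceps in early stance and flexors in late stance and swing,
a stance adduction moment (peak 6 N·m, set so the medial compartment
carries ~60–75% of the load, as instrumented-implant walking data show),
AP shear of ±0.12 BW and a 1.5 N·m transverse moment.  Seeded, bounded (uniform
coefficient, 3-harmonic Fourier) noise perturbs the curves without ever
violating the shape contract.  The "instrumented-implant-like" reference
force curves share the gait's axial load with a configurable medial share
(default 0.6) and exist to exercise the RMSE validation machinery; they
are not measurements, so RMSE values against them validate plumbing, not
the model.

What this synthetic stage does not emulate: subject-specific marker data,
GRFs and filtering; segment inertia (folded into the prescribed wrench);
inter-subject variability.  Passing tests therefore demonstrate the
*mechanistic* behaviour of the model — the direction and relative size of
tensioning and conformity effects — not subject-specific magnitudes.

## Experiment and outcome metrics

The sweep runs 11 pre-strain deltas × 2 conformities on the same gait
input (22 scenarios).  Per scenario: peak total/medial/lateral knee
contact force (BW), contact moments (N·m and BW·H), AP femoral shift at
toe-off (fixed at 63 %GC rather than event-detected, so the metric is
well-defined for any input), CoP shift at the baseline peak-force frame,
full-cycle AP CoP excursion per compartment (the cycle window is used
because the stance/swing split of this metric is a reporting choice),
peak PCL force, and rotation ranges.  Shifts are relative to the delta=0
scenario of the matching conformity.  A compartment's CoP enters the shift
and excursion statistics only when it carries at least 30 N — the pressure
centroid of a nearly unloaded compartment is not a meaningful contact
location, and instrumented-implant reports apply the same cutoff.  The asymmetry index
|shift(−d)|/|shift(+d)| quantifies the tight/loose asymmetry; values
below one mean releasing the PCL perturbs the joint less than tensioning
it.

## Known limitations

* Single generic geometry and attachment table; no subject-specific
  calibration, so absolute forces are indicative only.
* Rigid-tendon muscles without excitation dynamics; no co-contraction
  beyond what the minimum-activation criterion produces.
* Quasi-static frames; no wear, friction or fluid effects.
* The patellar suspension (retinacular ligaments + passive quadriceps
  tone) is stiffer than a minimal model would require; this is the
  physical counterpart of the patella's soft-tissue envelope and is what
  makes swing-phase patellar equilibrium well-posed.
* The elastic-foundation law ignores shear coupling between neighbouring
  springs; pressures near contact-patch edges are accurate only to the
  mesh scale.
* On a circular dish the centre of pressure is an amplified image of the
  femoral motion, with gain `R_dish / (R_dish − R_fem)` — about 2.5 for
  the standard insert against 1.4 for the low-conformity one.  The
  standard insert's smaller kinematic excursions are therefore multiplied
  by a larger gain, and the within-cycle CoP excursion contrast between
  conformities comes out mixed rather than uniformly favouring the
  low-conformity insert.  Real cruciate-retaining inserts are not
  circular dishes (flat central region, steep anterior lip), which keeps
  their CoP gain near one; that profile lies outside this package's
  parametric surface family, so conformity comparisons here are reliable
  for kinematics and contact forces but not for CoP excursion magnitudes.
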