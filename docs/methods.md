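# Methods

## The scapulothoracic joint as a mobilizer

Measuring scapular motion is hard: the scapula glides under muscle and
skin, so surface markers carry soft-tissue artifacts of up to several
centimetres, and Euler angles computed directly from marker triads
inherit that error in full.  `scapmob` implements the internal-coordinate
("mobilizer") formulation of the scapulothoracic joint: instead of
modelling the scapula as a free body pressed onto the thorax by
constraint equations, the joint *grants* exactly the physiologically
permissible motion.

A mobilizer is specified by four coupled maps between the parent joint
frame F (on the thorax, at the centre of a thoracic ellipsoid) and the
child joint frame M (on the scapula, at the AA/TS/AI centroid):

* `X(q)` — the transform of M in F,
* `H(q)` — the 6 x n matrix taking the generalized speeds `u` to the
  spatial velocity `{omega; v}` of M in F,
* `Hdot(q, u)` — its time derivative, so accelerations are
  `H udot + Hdot u`,
* `N(q)` — the coupling matrix with `qdot = N u`.

For the ellipsoid mobilizer the coordinates `q = (abduction, elevation,
upward rotation)` are body-fixed X-Y-Z Euler angles of M in F, and the
speeds are the angular velocity of M expressed in F (the same speeds as
a ball-and-socket).  The frame origin is slaved to the orientation,

    p(q) = diag(h, w, d) n(q),
    n(q) = (sin t2, -sin t1 cos t2, cos t1 cos t2),

with `(h, w, d)` the ellipsoid semi-axes along F's height, width and
depth directions; `n` is the child frame's Z axis, so `ndot = u x n`
exactly and

    H = [ I3 ; -diag(h, w, d) skew(n) ],
    Hdot = [ 0 ; -diag(h, w, d) skew(u x n) ].

Because `||n|| = 1`, the origin satisfies the implicit ellipsoid
equation identically for every q: position-level state propagation costs
three ordinary differential equations, where a free joint plus three
surface constraints would cost nine differential-algebraic equations.
Note that `n` is the *angle-parameterization* normal: it equals the true
(gradient) ellipsoid normal only in the spherical limit h = w = d.  That
is a deliberate property of the joint definition, not an approximation
we correct.

`N(q)` is the inverse of the parent-frame Euler-rate matrix for the
body-fixed X-Y-Z sequence; it is the identity at the zero pose and
carries a 1/cos(elevation) singularity at |elevation| = 90 deg, which
the code reports as an explicit `ElevationSingularityError` (the
shoulder never approaches it: scapular elevation stays within roughly
+-30 deg).  The frame convention matters: with parent-frame speeds, H as
above and this N are mutually consistent, which the test suite verifies
against finite differences of `X(q)` along `qdot = N u`.  The
body-frame Euler-rate matrix (which depends on the second and third
angles instead of the first and second) is *not* consistent with this H
and is not used.

A pin mobilizer about a user-settable winging axis (default: the
scapular joint frame's Y axis, lying in the scapular plane tangent to
the surface) is chained after the ellipsoid, presenting a single 4-dof
joint with coordinates (abduction, elevation, upward rotation, winging).
The pin adds no translation, so the joint origin stays on the surface
for all four coordinates.

## Shoulder model

Four segments — thorax (root, welded to ground), clavicle, scapula,
humerus — with ISB axes (X anterior, Y superior, Z to the subject's
right; right shoulder):

| joint | type | coordinates |
|---|---|---|
| sternoclavicular | universal (Y then X) | protraction, elevation |
| scapulothoracic | ellipsoid + winging pin | 4 (above) |
| glenohumeral | gimbal, body-fixed Y-X-Y | plane of elevation, elevation (negative = raising), internal rotation |
| acromioclavicular | 3-equation point constraint | closes the girdle loop |

9 mobilities, 3 constraint equations, net 6 dofs.  Sternoclavicular
axial rotation is deliberately absent (it cannot be measured reliably
and the conoid ligament limits it).  The glenohumeral gimbal is singular
at zero elevation, so the neutral pose rests at 10 deg of abduction;
inverse kinematics uses damped steps, which keeps the near-singular
directions benign.

Default anthropometry is an order-of-magnitude adult dataset (thorax
landmarks IJ/C7/T8; scapular blade with AA-TS spine 95 mm and AI 115 mm
inferior; humerus 290 mm to the epicondyle markers; masses 0.156 / 0.70
/ 2.05 kg for clavicle / scapula / humerus; thoracic ellipsoid semi-axes
0.15 / 0.12 / 0.095 m for height / width / depth).  These are shipped as
an overridable YAML configuration; every numerical guarantee in the
package is self-consistency of the pipeline against this generator, not
agreement with any particular subject.  The clavicle carries no markers;
its length and neutral orientation are derived so the acromioclavicular
loop closes exactly at the default pose, and they are re-derived
whenever scaling or surface fitting moves the scapula.

### Scaling and surface customization

Scaling multiplies geometry (marker stations, joint-frame placements,
COM, constraint stations, ellipsoid) by per-segment factors, and inertia
by factor squared with mass unchanged; factors can be derived from
static-pose target markers via inter-marker distance ratios.

The thoracic surface is customized from >= 9 static calibration poses by
bounded trust-region least squares over the ellipsoid *orientation and
radii* (the parameters marker error is most sensitive to), with per-pose
inverse kinematics inside the objective.  The centre is kept at its
landmark-calibrated location by default: over the patch of surface the
scapula actually visits, centre and radii trade off almost degenerately,
and freeing the centre turns millimetre marker noise into centimetre
radius errors.  `fit_center=True` restores the full 9-parameter fit.
Calibration poses should span abduction, elevation and upward rotation;
elevation extremes are what determine the superior-inferior radius.

## Dynamics

With so few bodies, the equations of motion are assembled explicitly in
mobility space and solved as a KKT system

    [ M   G^T ] [ udot   ]   [ f_applied - f_inertial ]
    [ G   0   ] [ lambda ] = [ b ],

where M comes from per-body spatial inertias projected through analytic
body Jacobians, `f_inertial` collects the velocity-product terms from
the bias accelerations (computed analytically through `Hdot`, never by
numerical differentiation), G is the acromioclavicular point-constraint
Jacobian and b its acceleration bias.  Joint reaction loads come from a
distal-to-proximal per-body Newton-Euler balance, reported as the total
wrench transmitted through each mobilizer about the joint frame origin
in ground, with the loop-constraint force `+-lambda` applied at the two
stations.

**Inverse-dynamics gauge.**  With a closed loop, `(f, lambda)` is a
3-parameter family for given `(q, u, udot)`: any `f + G^T mu` paired
with `lambda - mu` satisfies the same equations — physically, a rigid
closed linkage held statically is indeterminate.  `inverse_dynamics`
therefore accepts the multipliers as an input (pass the forward-dynamics
solution to close round trips exactly) and defaults to `lambda = 0`,
attributing the entire load to the reported generalized forces; at a
static pose this choice reproduces the gravitational potential gradient
exactly.  Generalized forces are conjugate to the mobilities
(`power = f . u`); since every mobility in this model is angular, all
generalized forces are torques.

**Inverse-dynamics pipeline.**  Coordinates are lowpass filtered
(3rd-order Butterworth, 2 Hz cut-off, applied forward-backward so the
zero-phase result does not bias accelerations), then interpolated by a
quintic smoothing spline whose smoothing factor is chosen by
cross-validation on held-out samples (a CV stand-in for classic
generalized cross-validation: the exact GCV trace is awkward for
B-spline smoothers, and on noise-free fixtures both degenerate to
near-interpolation, which the selector detects from the second-difference
noise estimate and short-circuits to s = 0).  First and second analytic
spline derivatives feed the per-frame inverse dynamics.  Because
filtering each coordinate independently moves the pose slightly off the
loop-closure manifold, each frame is re-projected (clavicle absorbing
the correction) before the balance is evaluated; violations beyond 1 mm
abort with the frame index.

**Forward dynamics.**  A 5-stage Runge-Kutta-Merson integrator with
embedded error control drives the simulation at a relative accuracy of
1e-4 (roughly four significant digits in the states); the step
controller uses a conservative safety factor of 0.7 and growth cap of
2.5, chosen so the energy drift of the conservative 2 s passive swing
stays a few times below the 0.1 % energy-drift target rather than at it.
After every accepted step, position- and velocity-level constraints are
projected (tolerance 0.01 mm).  Passive coordinate-limit springs are
one-sided exponentials `k (exp(c x) - 1 - c x)` (k = 2 N m, c = 20/rad)
— zero value *and* slope at the limit, so the force field is C1 and has
a closed-form potential, which makes total-energy monitoring exact.
Damping defaults to zero so the swing is conservative.

## Marker-based inverse kinematics

Each frame minimizes the weighted squared marker error over all nine
coordinates with the loop closure folded in as a heavily weighted
residual (weight 1e6 x the mean marker weight, so solutions are
invariant to a common rescaling of marker weights), followed by a Newton
projection; every reported frame satisfies the constraint far below
0.01 mm.  The optimizer is Levenberg-Marquardt-damped Gauss-Newton with
analytic marker Jacobians from the joint H matrices; steps are taken in
mobility space and mapped back through `N(q)`.  Convergence: step below
1e-10 rad (1e-7 inside the noise study, where the angle RMSEs are at the
0.1-10 deg scale) or 100 iterations.  Occluded samples are flagged and
given zero weight, never interpolated.  Trials solve frame-sequentially
with warm starts.

## The noise study

`synthesize_motion` builds smooth (sin^2-bump) coordinate profiles from
neutral to a task peak and back over 2 s — flexion, abduction, or
rotation at 90 deg abduction; flexion is dominated by scapular upward
rotation, peaking 27 deg above neutral — projects each frame onto the
constraint manifold, and generates markers at 120 Hz through forward
kinematics.  The trials are deliberately short; they compress the
neutral-peak-neutral arc of a laboratory trial into a desk-scale
computation, and all quantities reported from them are
self-consistency statistics, not laboratory values.

The soft-tissue-artifact model adds, per marker: a systematic bias along
one uniformly random unit direction held fixed for the trial, with
magnitude = level x a Gaussian time envelope peaking at maximum arm
elevation (sigma = trial duration / 6, so the bias is ~1 % of its peak
at the neutral static start and end postures); plus zero-mean white
noise at every sample with per-axis SD defaulting to 25 % of the level.
Levels span 1-40 mm.

Three estimates of scapular orientation are scored against the
noise-free reference by RMSE over the central portion of the trial
(0.25 s trimmed at each end against filter edge effects):

1. **direct** — ISB Y-X-Z angles from the AA/TS/AI and IJ/C7/T8 marker
   triads (thorax frame built from the triad, a variant of the ISB
   recommendation which also uses the xiphoid);
2. **model_euler** — the same triad construction applied to the model's
   markers after inverse kinematics;
3. **joint_coords** — the four scapulothoracic coordinates from the same
   IK.

The noisy markers are lowpass filtered once (3rd-order zero-phase
Butterworth, 5 Hz) and the identical filtered markers feed all three
routes.  Filtering only the direct route would conflate two different
questions — the geometric benefit of the joint model and the benefit of
temporal smoothing — because per-frame IK has no temporal coupling;
identical preprocessing isolates the model's contribution, which is the
comparison of interest.

Within a trial index, the offset directions and white-noise draws are
generated once and scaled by the level (common random numbers).  This
makes every method's mean-RMSE curve exactly monotone in the level,
which sharpens the 4.7 deg threshold crossings at a fixed trial budget
and lets `scripts/acceptance.py` locate the 1-mm crossings by bisection.

What the generator does and does not emulate: it produces rigid-body
marker sets with artifact statistics (fixed-direction bias + white
noise) on an idealized subject; it does not model marker occlusion,
non-Gaussian artifact waveforms, inter-marker artifact correlation from
actual skin mechanics, or anatomical variation.  Passing the study
therefore demonstrates the *mechanism* — restricting reconstruction to
the permissible-motion manifold attenuates artifact — and the relative
ordering of methods, not subject-specific error magnitudes.

## Known limitations

* The absolute noise-to-angle gain depends on the marker-triad lever
  arms and the bias-envelope width.  With this package's default
  anthropometry the direct method's mean scapular-angle RMSE grows at
  ~0.34 deg per mm of noise and crosses the 4.7 deg clinical threshold
  near 14 mm; bone-pin-subject studies report crossings near 8 mm, i.e.
  a ~1.7x higher gain, presumably reflecting that subject's triad
  geometry and artifact time course.  The *ratio* between the
  model-based and direct crossing levels (~2.5x) and the level-by-level
  RMSE reduction (~60-65 %) are the robust, geometry-insensitive
  outputs.
* The ellipsoid is a smooth convex stand-in for the rib cage; subjects
  with pronounced spinal curvature or pathology may not be well served
  by a single per-task ellipsoid.
* The inverse-dynamics torque attribution is gauge-dependent in the
  presence of the closed loop (see above); compare torques only under a
  stated gauge.
* Reaction loads include any actuation transmitted along the mobility
  directions; they are interbody wrenches, not isolated articular
  contact forces.
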