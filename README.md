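# scapmob

Internal-coordinate shoulder-girdle kinematics and dynamics, built
around a four-degree-of-freedom **scapulothoracic joint**.

Scapular motion is a standard clinical indicator for shoulder pathology,
but the scapula glides under muscle and skin, so surface-marker
measurements carry soft-tissue artifacts of up to several centimetres.
`scapmob` is for biomechanists and movement scientists who want to
reconstruct scapular kinematics (and compute the associated joint
torques and reaction loads) through a rigid-body model that only admits
physiologically possible scapular motion, rather than from raw marker
triads.

## The model

The scapulothoracic joint is a *mobilizer* — the dual of a constraint:
it grants the scapula exactly four coordinates instead of removing
degrees of freedom from a free body.  Kinematics between the thorax
joint frame F and the scapula joint frame M follow the four mobilizer
maps

    X(q),   {omega; v} = H(q) u,   A = H udot + Hdot u,   qdot = N(q) u.

Abduction and elevation place M on a thoracic ellipsoid like longitude
and latitude; upward rotation spins the scapula about the surface
normal; winging lifts the medial border about an in-plane axis.  The
origin is slaved to the orientation through

    p(q) = diag(h, w, d) n(q),      n = (sin t2, -sin t1 cos t2, cos t1 cos t2),

with ellipsoid semi-axes (h, w, d), so the scapula glides on the surface
with **three position ODEs and zero constraint equations** — a free
joint plus surface constraints would need nine differential-algebraic
equations and degrades the conditioning of the dynamics.

Around the joint sits a four-segment shoulder model (thorax, clavicle,
scapula, humerus; 9 mobilities, an acromioclavicular point constraint,
net 6 dofs), with marker-based weighted-least-squares inverse
kinematics, explicit KKT dynamics (mass matrix M, constraint Jacobian G,
multipliers lambda), per-body Newton-Euler reaction loads, a
Butterworth + cross-validated-quintic-spline inverse-dynamics pipeline,
and a Runge-Kutta-Merson forward-dynamics integrator with energy
monitoring.  A synthetic-motion generator plus a soft-tissue-artifact
noise model (Gaussian-envelope bias with fixed random direction per
marker per trial, plus white noise) reproduce the marker-noise
robustness study at desk scale.  See `docs/methods.md` for the science.

## Worked example

Generate a synthetic flexion trial, reconstruct it by inverse
kinematics, and run the noise study:

```
$ scapmob synth --task flexion --duration 2.0 --rate 120 --out-dir demo
$ scapmob ik --trc demo/flexion_markers.trc --out demo/ik.mot \
             --reference demo/flexion_coordinates.mot
scapmob INFO: marker AA RMS 0.000 mm
...
scapmob INFO: coordinate RMSE vs reference: 2.9e-09 rad
```

The reconstruction recovers the generating coordinates to ~3e-9 rad —
the joint coordinates are exactly identifiable from the nine markers.
Now the robustness study (this is the expensive step, a few minutes):

```
$ scapmob noise-study --task flexion --levels 5:40:5 --trials 20 --seed 0 \
          --out demo/noise.tsv --plot demo/noise.png
scapmob INFO: mean model-based RMSE reduction vs direct: 66.3%
```

The table reports, per noise level and method, the mean and SD (over 20
trials) of the scapular-angle RMSE in degrees.  At 20 mm of simulated
skin artifact, direct marker-triad Euler angles are off by 7.7 deg RMSE
while the model-based angles stay at 2.6 deg and the scapulothoracic
joint coordinates at 2.1 deg: restricting the reconstruction to the
permissible-motion manifold absorbs about two thirds of the artifact.
Inverse and forward dynamics:

```
$ scapmob id --coords demo/flexion_coordinates.mot --out demo/forces.sto
$ scapmob fd --task flexion --duration 2.0 --out demo/swing.sto \
             --energy-out demo/energy.sto
scapmob INFO: energy drift over 2.0 s: ... (0.04% of initial potential)
```

`forces.sto` holds the generalized torque for each of the nine
coordinates (for the flexion task, a sustained scapular elevation torque
against gravity plus an upward-rotation torque that grows with arm
elevation); the passive swing conserves total energy to well under 0.1 %
at the default integrator accuracy of 1e-4 with the loop closure held to
0.01 mm.

The same functionality is available as a library:

```python
from scapmob import build_default, synthesize_motion, solve_trial

model = build_default()
motion, markers = synthesize_motion(model, "flexion")
result = solve_trial(model, markers)          # inverse kinematics
upward = result.coordinate("st_upward_rotation")
```

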