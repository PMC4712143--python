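"""Mobilizers: internal-coordinate joint primitives.

A mobilizer is the dual of a constraint: instead of removing degrees of
freedom from a free body it *grants* 1-6 dofs to a body via four coupled
maps,

* ``X(q)``      -- transform of the child joint frame M in the parent
                   joint frame F,
* ``H(q)``      -- 6 x nu matrix mapping the generalized speeds u to the
                   spatial velocity ``{omega; v}`` of M in F (expressed
                   in F),
* ``Hdot(q,u)`` -- its time derivative, so that the spatial acceleration
                   is ``H @ udot + Hdot @ u``,
* ``N(q)``      -- nq x nu coupling matrix with ``qdot = N(q) @ u``.

The ellipsoid mobilizer couples the translation of the child frame to its
orientation so that the frame origin glides on an ellipsoid surface --
three ordinary differential equations instead of the nine
differential-algebraic equations a free joint plus three surface
constraints would need.  Chaining it with a pin about a user-settable
"winging" axis yields the 4-dof scapulothoracic joint.

Frame conventions for the ellipsoid mobilizer: the coordinates q are the
body-fixed X-Y-Z Euler angles (abduction, elevation, upward rotation) of
the child frame in F, and the speeds u are the components of the child
frame's angular velocity *expressed in F*; this is the convention under
which the angular block of H is the identity and the linear block is
``-diag(h, w, d) @ skew(n)``.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .spatial import Transform, axis_rotation, skew

__all__ = [
    "ElevationSingularityError",
    "Mobilizer",
    "MobilizerState",
    "PinMobilizer",
    "UniversalMobilizer",
    "GimbalMobilizer",
    "EllipsoidSurface",
    "EllipsoidMobilizer",
    "ScapulothoracicMobilizer",
    "ScapulothoracicCoordinates",
    "ellipsoid_translation",
    "surface_normal",
    "ellipsoid_H",
    "ellipsoid_Hdot",
    "coupling_N",
]

_EZ = np.array([0.0, 0.0, 1.0])


class ElevationSingularityError(ValueError):
    """Raised where the rate-coupling matrix degenerates (|elevation| -> 90 deg)."""


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length axis")
    return v / n


class Mobilizer(ABC):
    """Kinematic contract shared by every joint primitive."""

    nq: int
    nu: int

    @abstractmethod
    def transform(self, q: np.ndarray) -> Transform:
        """X(q): child joint frame M in parent joint frame F."""

    @abstractmethod
    def H(self, q: np.ndarray) -> np.ndarray:
        """6 x nu map from u to {omega; v} of M in F, expressed in F."""

    @abstractmethod
    def Hdot(self, q: np.ndarray, u: np.ndarray) -> np.ndarray:
        """Time derivative of H along the trajectory qdot = N u."""

    def N(self, q: np.ndarray) -> np.ndarray:
        """Rate-coupling matrix, qdot = N(q) u.  Identity by default."""
        return np.eye(self.nq)

    def qdot(self, q: np.ndarray, u: np.ndarray) -> np.ndarray:
        return self.N(q) @ u

    def u_from_qdot(self, q: np.ndarray, qdot: np.ndarray) -> np.ndarray:
        return np.linalg.solve(self.N(q), qdot)

    def udot_from_qddot(
        self, q: np.ndarray, qdot: np.ndarray, qddot: np.ndarray
    ) -> np.ndarray:
        """Generalized accelerations from coordinate accelerations.

        Default (N == I): udot = qddot.  Joints with configuration-dependent
        N override this with the analytic derivative.
        """
        return np.asarray(qddot, dtype=float)

    def check_state(self, q, u) -> None:
        q = np.asarray(q)
        u = np.asarray(u)
        if q.shape != (self.nq,) or u.shape != (self.nu,):
            raise ValueError(
                f"state shape mismatch: expected q({self.nq}), u({self.nu}), "
                f"got q{q.shape}, u{u.shape}"
            )


@dataclass
class MobilizerState:
    """Coordinates and speeds of one mobilizer (lengths must match its dofs)."""

    q: np.ndarray
    u: np.ndarray

    def __post_init__(self):
        self.q = np.atleast_1d(np.asarray(self.q, dtype=float))
        self.u = np.atleast_1d(np.asarray(self.u, dtype=float))


class PinMobilizer(Mobilizer):
    """1-dof rotation about a fixed axis (axis expressed in F and in M)."""

    nq = nu = 1

    def __init__(self, axis=(0.0, 0.0, 1.0)):
        self.axis = _unit(axis)

    def transform(self, q):
        return Transform(axis_rotation(self.axis, float(q[0])))

    def H(self, q):
        return np.concatenate([self.axis, np.zeros(3)]).reshape(6, 1)

    def Hdot(self, q, u):
        return np.zeros((6, 1))


class UniversalMobilizer(Mobilizer):
    """2-dof joint: rotation about axis1 then about the rotated axis2."""

    nq = nu = 2

    def __init__(self, axis1=(0.0, 1.0, 0.0), axis2=(1.0, 0.0, 0.0)):
        self.axis1 = _unit(axis1)
        self.axis2 = _unit(axis2)

    def transform(self, q):
        R = axis_rotation(self.axis1, q[0]) @ axis_rotation(self.axis2, q[1])
        return Transform(R)

    def H(self, q):
        R1 = axis_rotation(self.axis1, q[0])
        H = np.zeros((6, 2))
        H[:3, 0] = self.axis1
        H[:3, 1] = R1 @ self.axis2
        return H

    def Hdot(self, q, u):
        R1 = axis_rotation(self.axis1, q[0])
        Hd = np.zeros((6, 2))
        Hd[:3, 1] = u[0] * np.cross(self.axis1, R1 @ self.axis2)
        return Hd


class GimbalMobilizer(Mobilizer):
    """3-dof body-fixed rotation sequence (e.g. the ISB Y-X-Y glenohumeral joint).

    Speeds are the coordinate rates (N == I); the columns of H are the
    instantaneous rotation axes expressed in F.
    """

    nq = nu = 3

    def __init__(self, order: str = "YXY"):
        order = order.upper()
        if len(order) != 3 or any(c not in "XYZ" for c in order):
            raise ValueError(f"bad gimbal order {order!r}")
        self.order = order
        basis = {"X": [1.0, 0, 0], "Y": [0, 1.0, 0], "Z": [0, 0, 1.0]}
        self.axes = [np.array(basis[c]) for c in order]

    def transform(self, q):
        R = np.eye(3)
        for a, ang in zip(self.axes, q):
            R = R @ axis_rotation(a, ang)
        return Transform(R)

    def _frames(self, q):
        R1 = axis_rotation(self.axes[0], q[0])
        R12 = R1 @ axis_rotation(self.axes[1], q[1])
        return R1, R12

    def H(self, q):
        R1, R12 = self._frames(q)
        H = np.zeros((6, 3))
        H[:3, 0] = self.axes[0]
        H[:3, 1] = R1 @ self.axes[1]
        H[:3, 2] = R12 @ self.axes[2]
        return H

    def Hdot(self, q, u):
        R1, R12 = self._frames(q)
        a1 = self.axes[0]
        b2 = R1 @ self.axes[1]
        b3 = R12 @ self.axes[2]
        w1 = u[0] * a1
        w2 = w1 + u[1] * b2
        Hd = np.zeros((6, 3))
        Hd[:3, 1] = np.cross(w1, b2)
        Hd[:3, 2] = np.cross(w2, b3)
        return Hd


@dataclass
class EllipsoidSurface:
    """Thoracic gliding surface: radii along the joint-frame axes plus pose.

    ``radii = (h, w, d)`` are the semi-axes along the thorax joint frame's
    X (height), Y (width) and Z (depth) directions, in metres.  ``frame``
    places the ellipsoid centre (the parent joint frame F) in the thorax
    segment frame.
    """

    radii: tuple = (0.07, 0.10, 0.12)
    frame: Transform = field(default_factory=Transform.identity)

    def __post_init__(self):
        r = np.asarray(self.radii, dtype=float)
        if r.shape != (3,) or np.any(r <= 0):
            raise ValueError("ellipsoid radii must be three positive lengths")
        self.radii = tuple(r)

    @property
    def D(self) -> np.ndarray:
        return np.diag(self.radii)

    def implicit(self, p) -> float:
        """Value of (x/h)^2 + (y/w)^2 + (z/d)^2 at a point in the joint frame."""
        p = np.asarray(p, dtype=float)
        return float(np.sum((p / np.asarray(self.radii)) ** 2))


def surface_normal(q) -> np.ndarray:
    """Unit vector n(q) = (sin t2, -sin t1 cos t2, cos t1 cos t2) in F.

    This is the child frame's Z axis expressed in the thorax joint frame;
    the joint's angle parameterization treats it as the surface normal (it
    is the exact ellipsoid normal only in the spherical limit h = w = d,
    which is deliberate: the angle construction, not the gradient, defines
    the joint).
    """
    t1, t2 = q[0], q[1]
    s1, c1 = np.sin(t1), np.cos(t1)
    s2, c2 = np.sin(t2), np.cos(t2)
    return np.array([s2, -s1 * c2, c1 * c2])


def ellipsoid_translation(q, surf: EllipsoidSurface) -> np.ndarray:
    """Joint-frame origin on the ellipsoid: p = (h n1, w n2, d n3).

    The point satisfies the implicit surface equation identically, because
    ||n|| = 1.  Well defined for any angles; at |elevation| = 90 deg the
    point reaches the pole (h, 0, 0) while the *rate coupling* (see
    :func:`coupling_N`) degenerates.
    """
    return surf.D @ surface_normal(q)


def _euler_xyz(q) -> np.ndarray:
    return (
        axis_rotation("X", q[0]) @ axis_rotation("Y", q[1]) @ axis_rotation("Z", q[2])
    )


def ellipsoid_H(q, surf: EllipsoidSurface) -> np.ndarray:
    """6x3 mobilizer matrix: angular block I, linear block -D skew(n)."""
    n = surface_normal(q)
    H = np.zeros((6, 3))
    H[:3, :] = np.eye(3)
    H[3:, :] = -surf.D @ skew(n)
    return H


def ellipsoid_Hdot(q, u, surf: EllipsoidSurface) -> np.ndarray:
    """Time derivative of the ellipsoid H along qdot = N u.

    n is fixed in the child body, so ndot = u x n analytically (u is the
    angular velocity in F); no numerical differentiation is involved.
    """
    n = surface_normal(q)
    ndot = np.cross(np.asarray(u, dtype=float)[:3], n)
    Hd = np.zeros((6, 3))
    Hd[3:, :] = -surf.D @ skew(ndot)
    return Hd


def _rate_matrix_E(q) -> np.ndarray:
    """omega_F = E(q) qdot for the body-fixed X-Y-Z sequence."""
    t1, t2 = q[0], q[1]
    s1, c1 = np.sin(t1), np.cos(t1)
    s2, c2 = np.sin(t2), np.cos(t2)
    return np.array(
        [
            [1.0, 0.0, s2],
            [0.0, c1, -s1 * c2],
            [0.0, s1, c1 * c2],
        ]
    )


def coupling_N(q, tol: float = 1e-10) -> np.ndarray:
    """3x3 rate-coupling matrix for the ellipsoid mobilizer, qdot = N u.

    u is the angular velocity of the child frame expressed in the parent
    frame (the same speeds as a ball-and-socket), making N the inverse of
    the parent-frame Euler-rate matrix for the body-fixed X-Y-Z sequence.
    N(0) = I, and entries carrying 1/cos(elevation) diverge as
    |elevation| -> 90 deg, which is reported explicitly.
    """
    t1, t2 = q[0], q[1]
    s1, c1 = np.sin(t1), np.cos(t1)
    s2, c2 = np.sin(t2), np.cos(t2)
    if abs(c2) < tol:
        raise ElevationSingularityError(
            f"rate coupling singular: |elevation| = {np.degrees(abs(t2)):.3f} deg"
        )
    return np.array(
        [
            [1.0, s1 * s2 / c2, -c1 * s2 / c2],
            [0.0, c1, s1],
            [0.0, -s1 / c2, c1 / c2],
        ]
    )


class EllipsoidMobilizer(Mobilizer):
    """3-dof mobilizer gliding on an ellipsoid (abduction, elevation, upward rotation).

    Coordinates: body-fixed X-Y-Z Euler angles of the child joint frame in
    the parent (thorax) joint frame.  Speeds: angular velocity of the child
    frame expressed in the parent frame.  The frame origin is coupled to
    the orientation through p(q) = diag(h, w, d) n(q), so configuration
    propagates through exactly three ODEs -- no surface constraint
    equations exist.
    """

    nq = nu = 3

    def __init__(self, surface: EllipsoidSurface):
        self.surface = surface

    def transform(self, q):
        return Transform(_euler_xyz(q), ellipsoid_translation(q, self.surface))

    def H(self, q):
        return ellipsoid_H(q, self.surface)

    def Hdot(self, q, u):
        return ellipsoid_Hdot(q, u, self.surface)

    def N(self, q):
        return coupling_N(q)

    def u_from_qdot(self, q, qdot):
        return _rate_matrix_E(q) @ np.asarray(qdot, dtype=float)

    def udot_from_qddot(self, q, qdot, qddot):
        # u = E(q) qdot  ->  udot = E qddot + Edot qdot, with Edot analytic.
        t1, t2 = q[0], q[1]
        s1, c1 = np.sin(t1), np.cos(t1)
        s2, c2 = np.sin(t2), np.cos(t2)
        d1, d2 = qdot[0], qdot[1]
        Edot = np.array(
            [
                [0.0, 0.0, c2 * d2],
                [0.0, -s1 * d1, -c1 * d1 * c2 + s1 * s2 * d2],
                [0.0, c1 * d1, -s1 * d1 * c2 - c1 * s2 * d2],
            ]
        )
        return _rate_matrix_E(q) @ np.asarray(qddot, dtype=float) + Edot @ np.asarray(
            qdot, dtype=float
        )


@dataclass
class ScapulothoracicCoordinates:
    """The four scapulothoracic coordinates, radians.

    abduction/elevation locate the scapular joint frame on the thoracic
    ellipsoid (longitude/latitude); upward_rotation spins the scapula about
    the surface normal; winging lifts the medial border off the surface by
    rotating about an in-plane axis (default: joint-frame Y).
    """

    abduction: float = 0.0
    elevation: float = 0.0
    upward_rotation: float = 0.0
    winging: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.abduction, self.elevation, self.upward_rotation, self.winging]
        )

    @classmethod
    def from_array(cls, q) -> "ScapulothoracicCoordinates":
        q = np.asarray(q, dtype=float)
        return cls(*q.tolist())


class ScapulothoracicMobilizer(Mobilizer):
    """4-dof compound joint: ellipsoid mobilizer chained with a winging pin.

    Presents a single joint with coordinates (abduction, elevation,
    upward rotation, winging).  The pin axis lives in the intermediate
    (ellipsoid child) frame and is user-settable; the default Y axis lies
    in the scapular plane tangent to the surface.
    """

    nq = nu = 4

    def __init__(self, surface: EllipsoidSurface, winging_axis=(0.0, 1.0, 0.0)):
        self.surface = surface
        self.ellipsoid = EllipsoidMobilizer(surface)
        self.winging_axis = _unit(winging_axis)

    def transform(self, q):
        Xe = self.ellipsoid.transform(q[:3])
        Rw = axis_rotation(self.winging_axis, q[3])
        # pin adds no translation: origin stays on the ellipsoid surface
        return Transform(Xe.R @ Rw, Xe.p)

    def H(self, q):
        He = self.ellipsoid.H(q[:3])
        Re = _euler_xyz(q[:3])
        H = np.zeros((6, 4))
        H[:, :3] = He
        H[:3, 3] = Re @ self.winging_axis
        return H

    def Hdot(self, q, u):
        u = np.asarray(u, dtype=float)
        Hd = np.zeros((6, 4))
        Hd[:, :3] = self.ellipsoid.Hdot(q[:3], u[:3])
        Re = _euler_xyz(q[:3])
        Hd[:3, 3] = np.cross(u[:3], Re @ self.winging_axis)
        return Hd

    def N(self, q):
        N = np.eye(4)
        N[:3, :3] = self.ellipsoid.N(q[:3])
        return N

    def u_from_qdot(self, q, qdot):
        qdot = np.asarray(qdot, dtype=float)
        u = np.empty(4)
        u[:3] = self.ellipsoid.u_from_qdot(q[:3], qdot[:3])
        u[3] = qdot[3]
        return u

    def udot_from_qddot(self, q, qdot, qddot):
        udot = np.empty(4)
        udot[:3] = self.ellipsoid.udot_from_qddot(q[:3], qdot[:3], qddot[:3])
        udot[3] = qddot[3]
        return udot

    def coords_from_transform(self, X: Transform, guess=None) -> np.ndarray:
        """Invert the joint map: coordinates reproducing a reachable transform.

        Abduction/elevation come in closed form from the translation
        (n = D^-1 p); upward rotation and winging are recovered from the
        residual rotation by a two-variable least-squares refinement (exact
        to ~1e-12 for transforms on the joint's motion manifold).
        """
        n = np.linalg.solve(self.surface.D, X.p)
        nrm = np.linalg.norm(n)
        if abs(nrm - 1.0) > 1e-6:
            raise ValueError(
                "translation is not on the ellipsoid surface (|D^-1 p| = "
                f"{nrm:.6f}); not a scapulothoracic transform"
            )
        n = n / nrm
        t2 = np.arcsin(np.clip(n[0], -1.0, 1.0))
        t1 = np.arctan2(-n[1], n[2])
        Rxy = axis_rotation("X", t1) @ axis_rotation("Y", t2)
        Q = Rxy.T @ X.R  # = Rz(t3) @ Rot(winging_axis, t4)

        def resid(x):
            Rfit = axis_rotation("Z", x[0]) @ axis_rotation(self.winging_axis, x[1])
            M = Rfit.T @ Q
            return np.array([M[2, 1] - M[1, 2], M[0, 2] - M[2, 0], M[1, 0] - M[0, 1]])

        if guess is None:
            from scipy.spatial.transform import Rotation as _SR

            zyx = _SR.from_matrix(Q).as_euler("ZYX")
            x0 = np.array([zyx[0], zyx[1]])
        else:
            x0 = np.asarray(guess, dtype=float)[2:4]
        sol = least_squares(resid, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if np.linalg.norm(sol.fun) > 1e-8:
            raise ValueError("rotation not reachable by upward-rotation + winging")
        return np.array([t1, t2, sol.x[0], sol.x[1]])
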