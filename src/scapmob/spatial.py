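"""Rotation, rigid-transform and spatial (6-D) vector algebra.

Conventions used throughout the package:

* right-handed frames; ISB segment axes (X anterior, Y superior, Z to the
  subject's right);
* rotations are 3x3 orthogonal matrices mapping child-frame coordinates
  into the parent frame;
* Euler sequences are *body-fixed* (intrinsic) unless stated otherwise;
* angles are radians internally -- degrees appear only at file I/O
  boundaries;
* spatial vectors stack the angular part on top of the linear part,
  ``{omega; v}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation as _ScipyRotation

__all__ = [
    "GimbalLockError",
    "Transform",
    "axis_rotation",
    "euler_to_rotation",
    "rotation_to_euler",
    "is_rotation",
    "random_rotation",
    "skew",
]

_AXES = {
    "X": np.array([1.0, 0.0, 0.0]),
    "Y": np.array([0.0, 1.0, 0.0]),
    "Z": np.array([0.0, 0.0, 1.0]),
}

#: tolerance below which |cos(second angle)| (Tait-Bryan sequences) or
#: |sin(second angle)| (proper Euler sequences) is treated as gimbal lock
GIMBAL_TOL = 1e-8


class GimbalLockError(ValueError):
    """Raised when an Euler-angle extraction is requested at gimbal lock.

    Callers always receive this explicit signal rather than NaN angles.
    """


def skew(v: np.ndarray) -> np.ndarray:
    """Cross-product matrix: ``skew(a) @ b == np.cross(a, b)``."""
    x, y, z = v
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


def unskew(m: np.ndarray) -> np.ndarray:
    """Inverse of :func:`skew` (antisymmetric part is used)."""
    return 0.5 * np.array([m[2, 1] - m[1, 2], m[0, 2] - m[2, 0], m[1, 0] - m[0, 1]])


def axis_rotation(axis, angle: float) -> np.ndarray:
    """Rotation matrix about a single axis.

    ``axis`` is one of ``"X"/"Y"/"Z"`` or an arbitrary unit 3-vector.
    """
    if isinstance(axis, str):
        a = _AXES[axis.upper()]
    else:
        a = np.asarray(axis, dtype=float)
        a = a / np.linalg.norm(a)
    c, s = np.cos(angle), np.sin(angle)
    K = skew(a)
    return c * np.eye(3) + s * K + (1.0 - c) * np.outer(a, a)


def euler_to_rotation(order: str, angles) -> np.ndarray:
    """Body-fixed Euler sequence to rotation matrix.

    The result is the product of the three single-axis rotations taken in
    body-fixed order, e.g. ``"YXZ"`` gives ``Ry(a1) @ Rx(a2) @ Rz(a3)``.
    """
    order = order.upper()
    if len(order) != 3 or any(c not in "XYZ" for c in order):
        raise ValueError(f"unsupported Euler order {order!r}")
    angles = np.asarray(angles, dtype=float)
    if angles.shape != (3,) or not np.all(np.isfinite(angles)):
        raise ValueError("need three finite Euler angles")
    R = np.eye(3)
    for axis, ang in zip(order, angles):
        R = R @ axis_rotation(axis, ang)
    return R


def rotation_to_euler(R: np.ndarray, order: str, *, tol: float = GIMBAL_TOL) -> np.ndarray:
    """Extract body-fixed Euler angles; explicit error at gimbal lock.

    Satisfies ``euler_to_rotation(order, rotation_to_euler(R, order)) == R``
    to better than 1e-9 away from lock.  A Tait-Bryan sequence (three
    distinct axes) locks when ``|cos(second angle)| < tol``; a proper Euler
    sequence (first axis repeated) locks when ``|sin(second angle)| < tol``.
    """
    import warnings

    order = order.upper()
    with warnings.catch_warnings():
        # scipy warns at gimbal lock; we detect it and raise explicitly below
        warnings.simplefilter("ignore", UserWarning)
        angles = _ScipyRotation.from_matrix(np.asarray(R, dtype=float)).as_euler(order)
    proper = order[0] == order[2]
    second = angles[1]
    margin = abs(np.sin(second)) if proper else abs(np.cos(second))
    if margin < tol:
        raise GimbalLockError(
            f"Euler sequence {order} is at gimbal lock (second angle "
            f"{np.degrees(second):.6f} deg)"
        )
    return angles


def is_rotation(R: np.ndarray, tol: float = 1e-9) -> bool:
    """True if ``R`` is orthogonal with determinant +1 within ``tol``."""
    R = np.asarray(R)
    if R.shape != (3, 3):
        return False
    return (
        np.abs(R @ R.T - np.eye(3)).max() < tol
        and abs(np.linalg.det(R) - 1.0) < tol
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniformly distributed rotation matrix (for tests and fixtures)."""
    return _ScipyRotation.random(rng=rng).as_matrix()


@dataclass(frozen=True)
class Transform:
    """Rigid transform: rotation plus translation, ``y = R x + p``.

    Composition follows matrix convention: ``(A @ B)(x) == A(B(x))``.
    """

    R: np.ndarray = field(default_factory=lambda: np.eye(3))
    p: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "R", np.asarray(self.R, dtype=float))
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))

    @classmethod
    def identity(cls) -> "Transform":
        return cls()

    @classmethod
    def from_rotation(cls, R: np.ndarray) -> "Transform":
        return cls(R=R)

    @classmethod
    def from_translation(cls, p) -> "Transform":
        return cls(p=np.asarray(p, dtype=float))

    def compose(self, other: "Transform") -> "Transform":
        return Transform(self.R @ other.R, self.R @ other.p + self.p)

    __matmul__ = compose

    def inverse(self) -> "Transform":
        Rt = self.R.T
        return Transform(Rt, -Rt @ self.p)

    def apply(self, point) -> np.ndarray:
        """Map a point (or an (N,3) array of points) through the transform."""
        point = np.asarray(point, dtype=float)
        return point @ self.R.T + self.p

    def apply_vector(self, vec) -> np.ndarray:
        """Rotate a free vector (no translation)."""
        return np.asarray(vec, dtype=float) @ self.R.T

    def is_valid(self, tol: float = 1e-9) -> bool:
        return is_rotation(self.R, tol) and np.all(np.isfinite(self.p))

    def almost_equal(self, other: "Transform", tol: float = 1e-9) -> bool:
        return (
            np.abs(self.R - other.R).max() < tol
            and np.abs(self.p - other.p).max() < tol
        )
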