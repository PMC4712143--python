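"""ISB segment-frame constructions from bony-landmark triads.

Scapula frames are built from the Angulus Acromialis (AA), Trigonum
Spinae (TS) and Angulus Inferior (AI) landmarks; thorax frames from the
Incisura Jugularis (IJ), C7 and T8 landmarks (a triad variant of the ISB
recommendation, which also uses the Processus Xiphoideus).  Scapular
orientation relative to the thorax is reported as the body-fixed Y-X-Z
Euler sequence (internal rotation, downward rotation, posterior tilt).

All functions accept arrays with leading batch dimensions, so a whole
trial of marker frames is converted at once.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.transform import Rotation as _SR

__all__ = [
    "DegenerateTriadError",
    "scapula_rotation",
    "thorax_rotation",
    "relative_yxz_angles",
    "scapula_thorax_angles",
]

_COLLINEAR_TOL = 1e-10


class DegenerateTriadError(ValueError):
    """Raised when a landmark triad is (near-)collinear."""


def _normalize(v, what: str):
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n < _COLLINEAR_TOL):
        raise DegenerateTriadError(f"degenerate landmark triad: {what}")
    return v / n


def scapula_rotation(aa, ts, ai) -> np.ndarray:
    """ISB scapular frame from the AA/TS/AI triad (world -> columns X,Y,Z).

    Z along TS->AA (toward the acromion), X perpendicular to the AA/TS/AI
    plane pointing forward, Y = Z x X upward.
    """
    aa, ts, ai = (np.asarray(x, dtype=float) for x in (aa, ts, ai))
    z = _normalize(aa - ts, "AA-TS")
    x = _normalize(np.cross(aa - ts, ai - ts), "scapular plane")
    y = np.cross(z, x)
    return np.stack([x, y, z], axis=-1)


def thorax_rotation(ij, c7, t8) -> np.ndarray:
    """Thorax frame from IJ/C7/T8: Y from T8 toward the IJ/C7 midpoint, X forward."""
    ij, c7, t8 = (np.asarray(x, dtype=float) for x in (ij, c7, t8))
    y = _normalize(0.5 * (ij + c7) - t8, "thorax vertical")
    z = _normalize(np.cross(ij - c7, y), "thorax plane")
    x = np.cross(y, z)
    return np.stack([x, y, z], axis=-1)


def relative_yxz_angles(R_parent, R_child) -> np.ndarray:
    """Body-fixed Y-X-Z angles of child relative to parent (radians)."""
    R_parent = np.asarray(R_parent, dtype=float)
    R_child = np.asarray(R_child, dtype=float)
    R_rel = np.swapaxes(R_parent, -1, -2) @ R_child
    flat = R_rel.reshape(-1, 3, 3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # gimbal warnings handled by callers
        ang = _SR.from_matrix(flat).as_euler("YXZ")
    return ang.reshape(R_rel.shape[:-2] + (3,))


def scapula_thorax_angles(aa, ts, ai, ij, c7, t8) -> np.ndarray:
    """ISB Y-X-Z scapulothoracic angles straight from the six landmarks.

    Returns (..., 3): internal rotation (Y), downward rotation (X),
    posterior tilt (Z).  Invariant to any common rigid motion of all six
    landmarks.
    """
    return relative_yxz_angles(thorax_rotation(ij, c7, t8), scapula_rotation(aa, ts, ai))
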