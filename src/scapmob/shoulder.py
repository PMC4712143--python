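"""The four-segment shoulder model: build, scale, customize.

Topology (right shoulder, ISB ground axes X anterior / Y superior / Z
lateral, thorax welded to ground):

* thorax -> clavicle : universal joint at the sternoclavicular joint
  (protraction-retraction about Y, elevation-depression about the rotated
  X); axial rotation is deliberately absent,
* thorax -> scapula  : 4-dof scapulothoracic joint on the thoracic
  ellipsoid,
* scapula -> humerus : glenohumeral gimbal, body-fixed Y-X-Y (plane of
  elevation, elevation, internal rotation),
* clavicle <-> scapula : acromioclavicular ball joint as a 3-equation
  point constraint closing the shoulder-girdle loop.

That gives 2 + 4 + 3 = 9 mobilities, 3 constraint equations, net 6 dofs.

Default anthropometry (segment dimensions, inertial properties, ellipsoid
radii) is an order-of-magnitude adult dataset shipped as an overridable
configuration; every numerical guarantee in the package is
self-consistency against this generator, not agreement with any specific
subject.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation as _SR

from .ik import solve_frame
from .mobilizers import (
    EllipsoidSurface,
    GimbalMobilizer,
    PinMobilizer,
    ScapulothoracicMobilizer,
    UniversalMobilizer,
)
from .multibody import Body, Joint, ModelTree, PointConstraint
from .spatial import Transform, axis_rotation

__all__ = [
    "ScaleSpec",
    "build_default",
    "scale",
    "derive_scale_factors",
    "fit_ellipsoid",
    "to_config",
    "from_config",
    "MARKER_NAMES",
]

MARKER_NAMES = ("IJ", "C7", "T8", "AA", "TS", "AI", "GH", "EL", "EM")

# ----------------------------------------------------------- anthropometry
# Thorax landmarks in the thorax frame (origin mid-chest at IJ level), m.
_THORAX_MARKERS = {
    "IJ": (0.07, 0.0, 0.0),
    "C7": (-0.07, 0.03, 0.0),
    "T8": (-0.10, -0.18, 0.0),
}

# Ellipsoid joint frame T in the thorax: x_T superior (height axis h),
# y_T to the subject's left (width axis w), z_T posterior (depth axis d).
_R_THORAX_T = np.array(
    [
        [0.0, 0.0, -1.0],
        [1.0, 0.0, 0.0],
        [0.0, -1.0, 0.0],
    ]
)
_ELLIPSOID_CENTER = (0.0, -0.12, 0.0)
_ELLIPSOID_RADII = (0.15, 0.12, 0.095)

# Scapula blade template in the ISB scapular frame (origin AA, Z toward AA
# along the spine, X perpendicular to the blade): AA/TS/AI landmarks, the
# glenohumeral centre and the acromioclavicular station.
_SCAP_ISB = {
    "AA": (0.0, 0.0, 0.0),
    "TS": (0.0, 0.0, -0.095),
    "AI": (0.0, -0.115, -0.075),
    "GH_centre": (0.02, -0.035, -0.015),
    "AC": (0.0, 0.01, -0.01),
}

# Neutral scapulothoracic coordinates: the scapula resting posterolaterally
# on the thorax (abduction ~37 deg), spine near horizontal.
_NEUTRAL_ST = (0.64, 0.0, -1.40, 0.0)

_SC_LOCATION = (0.055, -0.01, 0.02)  # sternoclavicular joint in thorax frame
_NEUTRAL_GH = (0.0, -0.1745, 0.0)  # slight resting abduction avoids Y-X-Y lock

_SEGMENT_MASS = {"clavicle": 0.156, "scapula": 0.70, "humerus": 2.05}
_SEGMENT_INERTIA = {
    "clavicle": (3e-4, 3e-4, 2e-5),
    "scapula": (1.2e-3, 1.4e-3, 2.2e-3),
    "humerus": (1.9e-2, 4.0e-3, 1.9e-2),
}


def _scapula_frame_coords() -> dict:
    """Blade template re-expressed in the scapulothoracic joint frame S.

    S is the ISB scapular frame rotated -90 deg about Y (so upward
    rotation is positive about Z) with its origin moved to the AA/TS/AI
    centroid.
    """
    pts = {k: np.array(v, dtype=float) for k, v in _SCAP_ISB.items()}
    centroid = (pts["AA"] + pts["TS"] + pts["AI"]) / 3.0
    R = axis_rotation("Y", -np.pi / 2)
    return {k: R.T @ (v - centroid) for k, v in pts.items()}


def _sc_angles_for_direction(direction: np.ndarray) -> tuple:
    """Universal-joint angles (about Y then X) steering +Z onto a direction."""
    d = direction / np.linalg.norm(direction)
    elev = -np.arcsin(np.clip(d[1], -1.0, 1.0))
    prot = np.arctan2(d[0], d[2])
    return prot, elev


def _fit_clavicle(model: ModelTree) -> None:
    """(Re)derive clavicle length and neutral pose to close the AC loop exactly.

    The clavicle carries no markers; its geometry is defined by the
    sternoclavicular location and the scapular AC station at the default
    pose, which keeps the default pose an exact constraint solution.
    """
    qsl = model.q_slices()
    q = model.default_q.copy()
    # scapular AC station in ground at the default pose
    X = model.forward_kinematics(q)
    ac = next(c for c in model.constraints if c.name == "acromioclavicular")
    p_ac = X["scapula"].apply(ac.station_b)
    sc_joint = model.joint("sternoclavicular")
    p_sc = X["thorax"].apply(sc_joint.X_PF.p)
    vec = p_ac - p_sc
    length = float(np.linalg.norm(vec))
    prot, elev = _sc_angles_for_direction(vec)
    q[qsl["sternoclavicular"]] = (prot, elev)
    ac.station_a = np.array([0.0, 0.0, length])
    clav = model.bodies["clavicle"]
    clav.com = np.array([0.0, 0.0, length / 2.0])
    clav.markers = dict(clav.markers)
    model.default_q = q
    model.meta["clavicle_length"] = length


def build_default(gravity=(0.0, -9.80665, 0.0)) -> ModelTree:
    """Construct the default shoulder model at its neutral pose.

    The returned tree has 4 bodies, 9 mobilities and 3 constraint
    equations (net 6 dofs); ``model.default_q`` holds the neutral
    coordinates, at which the acromioclavicular constraint is satisfied
    exactly by construction.
    """
    thorax = Body(
        "thorax",
        markers={k: np.array(v) for k, v in _THORAX_MARKERS.items()},
    )
    model = ModelTree(thorax, gravity=gravity)

    surf = EllipsoidSurface(
        radii=_ELLIPSOID_RADII,
        frame=Transform(_R_THORAX_T, np.array(_ELLIPSOID_CENTER)),
    )
    scap_pts = _scapula_frame_coords()
    scapula = Body(
        "scapula",
        mass=_SEGMENT_MASS["scapula"],
        inertia=np.diag(_SEGMENT_INERTIA["scapula"]),
        com=np.array([-0.02, -0.02, 0.005]),
        markers={k: scap_pts[k] for k in ("AA", "TS", "AI")},
    )
    clavicle = Body(
        "clavicle",
        mass=_SEGMENT_MASS["clavicle"],
        inertia=np.diag(_SEGMENT_INERTIA["clavicle"]),
        com=np.array([0.0, 0.0, 0.08]),
    )
    humerus = Body(
        "humerus",
        mass=_SEGMENT_MASS["humerus"],
        inertia=np.diag(_SEGMENT_INERTIA["humerus"]),
        com=np.array([0.0, -0.16, 0.0]),
        markers={
            "GH": np.zeros(3),
            "EL": np.array([0.0, -0.29, 0.03]),
            "EM": np.array([0.0, -0.29, -0.03]),
        },
    )

    model.add_body(
        clavicle,
        Joint(
            "sternoclavicular",
            "thorax",
            "clavicle",
            UniversalMobilizer(axis1=(0, 1, 0), axis2=(1, 0, 0)),
            X_PF=Transform.from_translation(_SC_LOCATION),
            coord_names=("sc_protraction", "sc_elevation"),
        ),
    )
    model.add_body(
        scapula,
        Joint(
            "scapulothoracic",
            "thorax",
            "scapula",
            ScapulothoracicMobilizer(surf),
            X_PF=surf.frame,
            coord_names=(
                "st_abduction",
                "st_elevation",
                "st_upward_rotation",
                "st_winging",
            ),
        ),
    )

    # glenohumeral frame on the scapula, ground-aligned at the neutral pose
    q_st = np.array(_NEUTRAL_ST)
    st_mob = model.joint("scapulothoracic").mobilizer
    R_S = _R_THORAX_T @ st_mob.transform(q_st).R
    model.add_body(
        humerus,
        Joint(
            "glenohumeral",
            "scapula",
            "humerus",
            GimbalMobilizer("YXY"),
            X_PF=Transform(R_S.T, scap_pts["GH_centre"]),
            coord_names=("gh_plane", "gh_elevation", "gh_rotation"),
        ),
    )

    model.add_constraint(
        PointConstraint(
            "acromioclavicular",
            body_a="clavicle",
            station_a=np.array([0.0, 0.0, 0.15]),  # overwritten by _fit_clavicle
            body_b="scapula",
            station_b=scap_pts["AC"],
        )
    )

    q = np.zeros(model.nq)
    qsl = model.q_slices()
    q[qsl["scapulothoracic"]] = q_st
    q[qsl["glenohumeral"]] = _NEUTRAL_GH
    model.default_q = q
    _fit_clavicle(model)

    usl = model.u_slices()
    assembly_weights = np.ones(model.nu)
    assembly_weights[usl["sternoclavicular"]] = 1e-4  # clavicle absorbs closure
    neutral = model.default_q
    ranges = {
        "sc_protraction": (neutral[0] - 0.35, neutral[0] + 0.35),
        "sc_elevation": (neutral[1] - 0.35, neutral[1] + 0.35),
        "st_abduction": (q_st[0] - 0.35, q_st[0] + 0.60),
        "st_elevation": (-0.45, 0.45),
        "st_upward_rotation": (q_st[2] - 0.50, q_st[2] + 0.80),
        "st_winging": (-0.35, 0.35),
        "gh_plane": (-1.2, 2.0),
        "gh_elevation": (-2.6, -0.05),
        "gh_rotation": (-1.6, 1.6),
    }
    model.meta.update(
        surface=surf,
        scapulothoracic_joint="scapulothoracic",
        assembly_weights=assembly_weights,
        coord_ranges=ranges,
    )
    return model


# ------------------------------------------------------------------ scaling
@dataclass
class ScaleSpec:
    """Per-segment scale factors, or target static-pose marker positions.

    When only ``target_markers`` is given, factors are derived from the
    ratios of inter-marker distances (per segment).  The clavicle, which
    carries no markers, is re-derived from the scaled geometry so that the
    acromioclavicular loop stays exactly closed at the default pose.
    """

    factors: dict = field(default_factory=dict)
    target_markers: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, f in self.factors.items():
            if not np.isfinite(f) or f < 0.05:
                raise ValueError(f"degenerate scale factor for {name}: {f}")


def derive_scale_factors(model: ModelTree, target_markers: dict) -> dict:
    """Scale factors from pairwise inter-marker distances at the default pose."""
    pos = model.marker_positions(model.default_q)
    by_body: dict[str, list] = {}
    for m, b in model.marker_bodies().items():
        if m in target_markers:
            by_body.setdefault(b, []).append(m)
    factors = {}
    for b, names in by_body.items():
        if len(names) < 2:
            continue
        ratios = []
        for i in range(len(names)):
            for k in range(i + 1, len(names)):
                d_model = np.linalg.norm(pos[names[i]] - pos[names[k]])
                d_target = np.linalg.norm(
                    np.asarray(target_markers[names[i]])
                    - np.asarray(target_markers[names[k]])
                )
                ratios.append(d_target / d_model)
        factors[b] = float(np.mean(ratios))
    return factors


def scale(model: ModelTree, spec: ScaleSpec) -> ModelTree:
    """Scaled copy of the model (geometry x s, inertia x s^2, mass kept).

    Marker stations, joint-frame placements, COM locations, constraint
    stations and the thoracic ellipsoid all scale with their segment's
    factor; inertia follows the mass x length^2 rule.
    """
    factors = dict(spec.factors)
    if spec.target_markers:
        derived = derive_scale_factors(model, spec.target_markers)
        for b, f in derived.items():
            factors.setdefault(b, f)
    for name, f in factors.items():
        if not np.isfinite(f) or f < 0.05:
            raise ValueError(f"degenerate scale factor for {name}: {f}")
    out = copy.deepcopy(model)
    get = lambda b: factors.get(b, 1.0)
    for body in out.bodies.values():
        s = get(body.name)
        if s == 1.0:
            continue
        body.com = body.com * s
        body.markers = {k: v * s for k, v in body.markers.items()}
        body.inertia = body.inertia * s * s
    for j in out.joints:
        sp, sc = get(j.parent), get(j.child)
        j.X_PF = Transform(j.X_PF.R, j.X_PF.p * sp)
        j.X_BM = Transform(j.X_BM.R, j.X_BM.p * sc)
        mob = j.mobilizer
        if isinstance(mob, ScapulothoracicMobilizer) and sp != 1.0:
            surf = EllipsoidSurface(
                radii=tuple(np.asarray(mob.surface.radii) * sp),
                frame=Transform(mob.surface.frame.R, mob.surface.frame.p * sp),
            )
            j.mobilizer = ScapulothoracicMobilizer(surf, mob.winging_axis)
            out.meta["surface"] = surf
    for c in out.constraints:
        c.station_a = c.station_a * get(c.body_a)
        c.station_b = c.station_b * get(c.body_b)
    _fit_clavicle(out)
    return out


# ---------------------------------------------------------- ellipsoid fit
def fit_ellipsoid(
    model: ModelTree,
    marker_poses: list,
    radii_bounds=(0.02, 0.40),
    fit_center: bool = False,
    xtol: float = 1e-12,
    max_nfev: int | None = None,
):
    """Subject-specific thoracic surface from static marker poses.

    Adjusts the ellipsoid orientation and radii -- the parameters marker
    errors are most sensitive to -- to minimize the summed squared marker
    error of per-pose inverse kinematics across at least nine poses
    spanning the task range.  The centre stays at its landmark-calibrated
    location by default because centre and radii trade off almost
    degenerately over the patch of surface the scapula actually visits;
    pass ``fit_center=True`` for the full 9-parameter customization.
    Returns ``(surface, fitted_model, result)``; the fit objective is
    non-increasing across iterations (trust-region least squares).
    """
    if len(marker_poses) < 9:
        raise ValueError(
            f"ellipsoid fit is underdetermined with {len(marker_poses)} poses; "
            "need at least 9"
        )
    base = model
    st0 = base.joint("scapulothoracic")
    mob0 = st0.mobilizer
    R0 = st0.X_PF.R
    c0 = st0.X_PF.p
    r0 = np.asarray(mob0.surface.radii)

    work = copy.deepcopy(base)  # private scratch model, mutated per candidate

    def make_model(x, scratch=True):
        m = work if scratch else copy.deepcopy(base)
        st = m.joint("scapulothoracic")
        R = R0 @ _SR.from_rotvec(x[:3]).as_matrix()
        centre = x[6:9] if fit_center else c0
        surf = EllipsoidSurface(radii=tuple(x[3:6]), frame=Transform(R, centre))
        st.mobilizer = ScapulothoracicMobilizer(surf, mob0.winging_axis)
        st.X_PF = surf.frame
        m.meta["surface"] = surf
        m.default_q = base.default_q.copy()
        _fit_clavicle(m)
        return m

    warm = {"q": [None] * len(marker_poses)}

    def residuals(x):
        m = make_model(x)
        res = []
        for i, pose in enumerate(marker_poses):
            q0 = warm["q"][i]
            try:
                q, info = solve_frame(m, pose, q_warm=q0)
            except Exception:
                res.append(np.full(3 * len(pose), 1.0))
                continue
            warm["q"][i] = q
            pos = m.marker_positions(q)
            res.append(
                np.concatenate(
                    [pos[n] - np.asarray(p) for n, p in pose.items() if n in pos]
                )
            )
        return np.concatenate(res)

    x0 = np.concatenate([np.zeros(3), r0])
    lb = np.concatenate([-0.6 * np.ones(3), radii_bounds[0] * np.ones(3)])
    ub = np.concatenate([0.6 * np.ones(3), radii_bounds[1] * np.ones(3)])
    if fit_center:
        x0 = np.concatenate([x0, c0])
        lb = np.concatenate([lb, c0 - 0.1])
        ub = np.concatenate([ub, c0 + 0.1])
    result = least_squares(
        residuals, x0, bounds=(lb, ub), xtol=xtol, ftol=1e-14, gtol=1e-14,
        diff_step=1e-5, max_nfev=max_nfev,
    )
    fitted = make_model(result.x, scratch=False)
    return fitted.meta["surface"], fitted, result


# -------------------------------------------------------- serialization
_MOBILIZER_TAGS = {
    PinMobilizer: "pin",
    UniversalMobilizer: "universal",
    GimbalMobilizer: "gimbal",
    ScapulothoracicMobilizer: "scapulothoracic",
}


def _transform_to_cfg(X: Transform) -> dict:
    return {
        "rotvec": _SR.from_matrix(X.R).as_rotvec().tolist(),
        "translation": X.p.tolist(),
    }


def _transform_from_cfg(d: dict) -> Transform:
    return Transform(
        _SR.from_rotvec(np.asarray(d["rotvec"], dtype=float)).as_matrix(),
        np.asarray(d["translation"], dtype=float),
    )


def _mobilizer_to_cfg(mob) -> dict:
    tag = _MOBILIZER_TAGS[type(mob)]
    cfg = {"type": tag}
    if tag == "pin":
        cfg["axis"] = mob.axis.tolist()
    elif tag == "universal":
        cfg["axis1"] = mob.axis1.tolist()
        cfg["axis2"] = mob.axis2.tolist()
    elif tag == "gimbal":
        cfg["order"] = mob.order
    elif tag == "scapulothoracic":
        cfg["radii"] = [float(r) for r in mob.surface.radii]
        cfg["surface_frame"] = _transform_to_cfg(mob.surface.frame)
        cfg["winging_axis"] = mob.winging_axis.tolist()
    return cfg


def _mobilizer_from_cfg(cfg: dict):
    tag = cfg["type"]
    if tag == "pin":
        return PinMobilizer(cfg["axis"])
    if tag == "universal":
        return UniversalMobilizer(cfg["axis1"], cfg["axis2"])
    if tag == "gimbal":
        return GimbalMobilizer(cfg["order"])
    if tag == "scapulothoracic":
        surf = EllipsoidSurface(
            radii=tuple(cfg["radii"]),
            frame=_transform_from_cfg(cfg["surface_frame"]),
        )
        return ScapulothoracicMobilizer(surf, cfg["winging_axis"])
    raise ValueError(f"unknown mobilizer type {tag!r}")


def to_config(model: ModelTree) -> dict:
    """Plain-data description of the model (YAML-serializable)."""
    cfg = {
        "gravity": model.gravity.tolist(),
        "root": model.root.name,
        "bodies": {},
        "joints": [],
        "constraints": [],
        "default_q": model.default_q.tolist(),
        "coord_ranges": {
            k: [float(a), float(b)]
            for k, (a, b) in model.meta.get("coord_ranges", {}).items()
        },
    }
    for b in model.bodies.values():
        cfg["bodies"][b.name] = {
            "mass": float(b.mass),
            "inertia": b.inertia.tolist(),
            "com": b.com.tolist(),
            "markers": {k: v.tolist() for k, v in b.markers.items()},
        }
    for j in model.joints:
        cfg["joints"].append(
            {
                "name": j.name,
                "parent": j.parent,
                "child": j.child,
                "mobilizer": _mobilizer_to_cfg(j.mobilizer),
                "X_PF": _transform_to_cfg(j.X_PF),
                "X_BM": _transform_to_cfg(j.X_BM),
                "coord_names": list(j.coord_names),
            }
        )
    for c in model.constraints:
        cfg["constraints"].append(
            {
                "name": c.name,
                "body_a": c.body_a,
                "station_a": c.station_a.tolist(),
                "body_b": c.body_b,
                "station_b": c.station_b.tolist(),
            }
        )
    return cfg


def from_config(cfg: dict) -> ModelTree:
    """Rebuild a model from :func:`to_config` output."""
    bodies = {
        name: Body(
            name,
            mass=bc["mass"],
            inertia=np.asarray(bc["inertia"], dtype=float),
            com=np.asarray(bc["com"], dtype=float),
            markers={k: np.asarray(v) for k, v in bc.get("markers", {}).items()},
        )
        for name, bc in cfg["bodies"].items()
    }
    model = ModelTree(bodies[cfg["root"]], gravity=cfg["gravity"])
    for jc in cfg["joints"]:
        mob = _mobilizer_from_cfg(jc["mobilizer"])
        joint = Joint(
            jc["name"],
            jc["parent"],
            jc["child"],
            mob,
            X_PF=_transform_from_cfg(jc["X_PF"]),
            X_BM=_transform_from_cfg(jc["X_BM"]),
            coord_names=tuple(jc["coord_names"]),
        )
        model.add_body(bodies[jc["child"]], joint)
        if isinstance(mob, ScapulothoracicMobilizer):
            model.meta["surface"] = mob.surface
            model.meta["scapulothoracic_joint"] = jc["name"]
    for cc in cfg.get("constraints", []):
        model.add_constraint(
            PointConstraint(
                cc["name"], cc["body_a"], cc["station_a"], cc["body_b"], cc["station_b"]
            )
        )
    model.default_q = np.asarray(cfg["default_q"], dtype=float)
    model.meta["coord_ranges"] = {
        k: tuple(v) for k, v in cfg.get("coord_ranges", {}).items()
    }
    usl = model.u_slices()
    w = np.ones(model.nu)
    if "sternoclavicular" in usl:
        w[usl["sternoclavicular"]] = 1e-4
    model.meta["assembly_weights"] = w
    return model
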