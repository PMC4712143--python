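"""Multibody tree: recursive kinematics, assembled dynamics, reaction loads.

A model is a tree of rigid bodies connected by mobilizers, rooted at a
body welded to ground (the thorax in the shoulder model), optionally
closed by point constraints (the acromioclavicular ball joint constrains
the three translations between a clavicle station and a scapula station).

Dynamics are assembled explicitly in mobility space and solved as the
KKT system

    [ M   G^T ] [ udot   ]   [ f_applied - f_inertial ]
    [ G   0   ] [ lambda ] = [ b                      ]

which is transparent and amply fast for a handful of bodies; the
per-body Newton-Euler balance is retained as the route to joint reaction
loads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mobilizers import Mobilizer
from .spatial import Transform, skew

__all__ = [
    "Body",
    "Joint",
    "PointConstraint",
    "ModelTree",
    "SystemDynamics",
    "ReactionLoad",
    "AssemblyError",
    "RedundantConstraintError",
]


def _cross(a, b) -> np.ndarray:
    # np.cross has substantial per-call overhead for single 3-vectors;
    # the kinematic recursions sit on the IK hot path.
    return np.array(
        [
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        ]
    )


class AssemblyError(RuntimeError):
    """Constraint assembly failed to converge; carries the residual (m)."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


class RedundantConstraintError(RuntimeError):
    """Constraint Jacobian is rank deficient (redundant constraints)."""


@dataclass
class Body:
    """Rigid segment: mass properties and attached markers (body frame, m)."""

    name: str
    mass: float = 0.0
    inertia: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    com: np.ndarray = field(default_factory=lambda: np.zeros(3))
    markers: dict = field(default_factory=dict)

    def __post_init__(self):
        self.inertia = np.asarray(self.inertia, dtype=float)
        if self.inertia.shape == (3,):
            self.inertia = np.diag(self.inertia)
        self.com = np.asarray(self.com, dtype=float)
        self.markers = {k: np.asarray(v, dtype=float) for k, v in self.markers.items()}
        self.validate()

    def validate(self):
        if self.mass < 0:
            raise ValueError(f"body {self.name}: negative mass")
        I = self.inertia
        if np.abs(I - I.T).max() > 1e-12:
            raise ValueError(f"body {self.name}: inertia not symmetric")
        ev = np.linalg.eigvalsh(I)
        if ev[0] < -1e-12:
            raise ValueError(f"body {self.name}: inertia not positive semidefinite")
        # principal-moment triangle inequalities
        a, b, c = np.sort(ev)
        if a + b < c - 1e-12:
            raise ValueError(f"body {self.name}: inertia violates triangle inequality")


@dataclass
class Joint:
    """Mobilized connection of ``child`` to ``parent``.

    ``X_PF`` places the parent joint frame F in the parent body frame;
    ``X_BM`` places the child joint frame M in the child body frame.
    """

    name: str
    parent: str
    child: str
    mobilizer: Mobilizer
    X_PF: Transform = field(default_factory=Transform.identity)
    X_BM: Transform = field(default_factory=Transform.identity)
    coord_names: tuple = ()

    def __post_init__(self):
        if not self.coord_names:
            self.coord_names = tuple(
                f"{self.name}_q{i}" for i in range(self.mobilizer.nq)
            )
        if len(self.coord_names) != self.mobilizer.nq:
            raise ValueError(f"joint {self.name}: coord_names length mismatch")


@dataclass
class PointConstraint:
    """Coincidence of a station on body A with a station on body B (3 equations)."""

    name: str
    body_a: str
    station_a: np.ndarray
    body_b: str
    station_b: np.ndarray

    def __post_init__(self):
        self.station_a = np.asarray(self.station_a, dtype=float)
        self.station_b = np.asarray(self.station_b, dtype=float)


@dataclass
class SystemDynamics:
    """Assembled Eq-of-motion quantities and the KKT solution."""

    M: np.ndarray
    G: np.ndarray
    b: np.ndarray
    f_applied: np.ndarray
    f_inertial: np.ndarray
    multipliers: np.ndarray
    udot: np.ndarray

    def residuals(self):
        """(dynamics, constraint) residuals of Eqs 10a/10b, absolute."""
        r1 = self.M @ self.udot + self.G.T @ self.multipliers - (
            self.f_applied - self.f_inertial
        )
        r2 = self.G @ self.udot - self.b if self.G.size else np.zeros(0)
        return r1, r2


@dataclass
class ReactionLoad:
    """Spatial load transmitted to the child across a joint, in ground.

    ``moment`` (N m) is taken about ``point`` (the joint M-frame origin in
    ground); ``force`` in N.  This is the total interbody wrench through
    the mobilizer, including any actuation along the mobility directions.
    """

    joint: str
    moment: np.ndarray
    force: np.ndarray
    point: np.ndarray


class _BodyKin:
    """Per-body kinematic scratchpad filled by the outward recursion."""

    __slots__ = ("X", "w", "v", "alpha_bias", "a_bias", "J", "p_M")

    def __init__(self):
        self.X = Transform.identity()
        self.w = np.zeros(3)
        self.v = np.zeros(3)
        self.alpha_bias = np.zeros(3)
        self.a_bias = np.zeros(3)
        self.J = None
        self.p_M = np.zeros(3)


class ModelTree:
    """Tree of bodies and mobilizers with optional loop-closing constraints."""

    def __init__(self, root: Body, gravity=(0.0, -9.80665, 0.0)):
        self.root = root
        self.bodies = {root.name: root}
        self.joints: list[Joint] = []
        self.constraints: list[PointConstraint] = []
        self.gravity = np.asarray(gravity, dtype=float)
        self._parent_joint: dict[str, Joint] = {}
        self.default_q = np.zeros(0)
        self.meta: dict = {}

    # ------------------------------------------------------------------ build
    def add_body(self, body: Body, joint: Joint) -> None:
        if joint.parent not in self.bodies:
            raise ValueError(f"unknown parent body {joint.parent!r}")
        if body.name in self.bodies:
            raise ValueError(f"duplicate body {body.name!r}")
        if joint.child != body.name:
            raise ValueError("joint.child must name the body being added")
        self.bodies[body.name] = body
        self.joints.append(joint)
        self._parent_joint[body.name] = joint
        self.default_q = np.concatenate([self.default_q, np.zeros(joint.mobilizer.nq)])

    def add_constraint(self, constraint: PointConstraint) -> None:
        for bn in (constraint.body_a, constraint.body_b):
            if bn not in self.bodies:
                raise ValueError(f"constraint references unknown body {bn!r}")
        self.constraints.append(constraint)

    # -------------------------------------------------------------- indexing
    @property
    def nq(self) -> int:
        return sum(j.mobilizer.nq for j in self.joints)

    @property
    def nu(self) -> int:
        return sum(j.mobilizer.nu for j in self.joints)

    @property
    def n_constraint_equations(self) -> int:
        return 3 * len(self.constraints)

    @property
    def coordinate_names(self) -> list:
        names = []
        for j in self.joints:
            names.extend(j.coord_names)
        return names

    def q_slices(self) -> dict:
        out, i = {}, 0
        for j in self.joints:
            out[j.name] = slice(i, i + j.mobilizer.nq)
            i += j.mobilizer.nq
        return out

    def u_slices(self) -> dict:
        out, i = {}, 0
        for j in self.joints:
            out[j.name] = slice(i, i + j.mobilizer.nu)
            i += j.mobilizer.nu
        return out

    def joint(self, name: str) -> Joint:
        for j in self.joints:
            if j.name == name:
                return j
        raise KeyError(name)

    # ----------------------------------------------------- rate conversions
    def qdot(self, q, u) -> np.ndarray:
        out = np.empty(self.nq)
        for j, qs, us in self._iter_slices():
            out[qs] = j.mobilizer.qdot(q[qs], u[us])
        return out

    def u_from_qdot(self, q, qdot) -> np.ndarray:
        out = np.empty(self.nu)
        for j, qs, us in self._iter_slices():
            out[us] = j.mobilizer.u_from_qdot(q[qs], qdot[qs])
        return out

    def udot_from_qddot(self, q, qdot, qddot) -> np.ndarray:
        out = np.empty(self.nu)
        for j, qs, us in self._iter_slices():
            out[us] = j.mobilizer.udot_from_qddot(q[qs], qdot[qs], qddot[qs])
        return out

    def _iter_slices(self):
        iq = iu = 0
        for j in self.joints:
            qs = slice(iq, iq + j.mobilizer.nq)
            us = slice(iu, iu + j.mobilizer.nu)
            yield j, qs, us
            iq, iu = qs.stop, us.stop

    # ------------------------------------------------------------ kinematics
    def _kinematics(self, q, u=None, want_jacobian=False):
        """Outward recursion: transforms, Jacobians and (if u is given)
        velocities and bias accelerations."""
        q = np.asarray(q, dtype=float)
        want_vel = u is not None
        if want_vel:
            u = np.asarray(u, dtype=float)
        kin = {self.root.name: _BodyKin()}
        if want_jacobian:
            kin[self.root.name].J = np.zeros((6, self.nu))
        for j, qs, us in self._iter_slices():
            mob = j.mobilizer
            qj = q[qs]
            pk = kin[j.parent]
            bk = _BodyKin()

            Rp, pp = pk.X.R, pk.X.p
            R = Rp @ j.X_PF.R  # ground orientation of joint frame F
            p_F = Rp @ j.X_PF.p + pp
            Xrel = mob.transform(qj)
            R_GM = R @ Xrel.R
            p_M = R @ Xrel.p + p_F
            RBM, pBM = j.X_BM.R, j.X_BM.p
            R_GB = R_GM @ RBM.T
            p_B = p_M - R_GB @ pBM
            bk.X = Transform(R_GB, p_B)
            bk.p_M = p_M

            if want_vel or want_jacobian:
                H = mob.H(qj)
                RHw = R @ H[:3]
                RHv = R @ H[3:]
                r_PB = p_B - pp
                r_MB = p_B - p_M

            if want_vel:
                uj = u[us]
                w_rel = RHw @ uj
                bk.w = pk.w + w_rel
                v_rel = RHv @ uj
                bk.v = pk.v + _cross(pk.w, r_PB) + v_rel + _cross(w_rel, r_MB)

                Hd = mob.Hdot(qj, uj)
                alpha_rel = _cross(pk.w, w_rel) + R @ (Hd[:3] @ uj)
                bk.alpha_bias = pk.alpha_bias + alpha_rel
                bk.a_bias = (
                    pk.a_bias
                    + _cross(pk.alpha_bias, r_PB)
                    + _cross(pk.w, bk.v - pk.v)
                    + _cross(pk.w, v_rel)
                    + R @ (Hd[3:] @ uj)
                    + _cross(alpha_rel, r_MB)
                    + _cross(w_rel, _cross(bk.w, r_MB))
                )

            if want_jacobian:
                J = np.empty((6, self.nu))
                J[:3] = pk.J[:3]
                J[3:] = pk.J[3:] - skew(r_PB) @ pk.J[:3]
                J[:3, us] += RHw
                J[3:, us] += RHv - skew(r_MB) @ RHw
                bk.J = J

            kin[j.child] = bk
        return kin

    def forward_kinematics(self, q) -> dict:
        """World transform of every body (tree recursion of Eqs 1/5)."""
        return {name: bk.X for name, bk in self._kinematics(q).items()}

    def marker_positions(self, q) -> dict:
        """World positions of all attached markers at configuration q."""
        X = self.forward_kinematics(q)
        out = {}
        for body in self.bodies.values():
            for mname, station in body.markers.items():
                out[mname] = X[body.name].apply(station)
        return out

    def marker_bodies(self) -> dict:
        return {
            m: b.name for b in self.bodies.values() for m in b.markers
        }

    @staticmethod
    def _point_state(bk: _BodyKin, station) -> tuple:
        rs = bk.X.R @ np.asarray(station, dtype=float)
        p = bk.X.p + rs
        return p, rs

    def _point_jacobian(self, bk: _BodyKin, station) -> np.ndarray:
        _, rs = self._point_state(bk, station)
        return bk.J[3:] - skew(rs) @ bk.J[:3]

    def _point_bias_accel(self, bk: _BodyKin, station) -> np.ndarray:
        _, rs = self._point_state(bk, station)
        return bk.a_bias + np.cross(bk.alpha_bias, rs) + np.cross(
            bk.w, np.cross(bk.w, rs)
        )

    def marker_jacobians(self, q) -> tuple:
        """(positions dict, 3xnu Jacobian dict) for all markers (mobility space)."""
        kin = self._kinematics(q, want_jacobian=True)
        pos, jac = {}, {}
        for body in self.bodies.values():
            bk = kin[body.name]
            for mname, station in body.markers.items():
                pos[mname] = bk.X.apply(station)
                jac[mname] = self._point_jacobian(bk, station)
        return pos, jac

    # ----------------------------------------------------------- constraints
    def constraint_error(self, q) -> np.ndarray:
        if not self.constraints:
            return np.zeros(0)
        X = self.forward_kinematics(q)
        err = []
        for c in self.constraints:
            pa = X[c.body_a].apply(c.station_a)
            pb = X[c.body_b].apply(c.station_b)
            err.append(pa - pb)
        return np.concatenate(err)

    def _constraint_matrices(self, kin) -> tuple:
        m = self.n_constraint_equations
        G = np.zeros((m, self.nu))
        bias = np.zeros(m)
        for i, c in enumerate(self.constraints):
            ka, kb = kin[c.body_a], kin[c.body_b]
            rows = slice(3 * i, 3 * i + 3)
            G[rows] = self._point_jacobian(ka, c.station_a) - self._point_jacobian(
                kb, c.station_b
            )
            bias[rows] = -(
                self._point_bias_accel(ka, c.station_a)
                - self._point_bias_accel(kb, c.station_b)
            )
        return G, bias

    def constraint_jacobian(self, q) -> np.ndarray:
        kin = self._kinematics(q, want_jacobian=True)
        return self._constraint_matrices(kin)[0]

    def assemble(self, q_guess, weights=None, tol=1e-9, maxiter=100) -> np.ndarray:
        """Project q onto the constraint manifold (Newton, weighted min-norm).

        ``weights`` (length nu) penalize moving each mobility; small weights
        mark coordinates that should absorb the correction (e.g. the
        clavicle when closing the acromioclavicular loop).  Converges well
        below the 0.01 mm tolerance the dynamics pipeline requires;
        raises :class:`AssemblyError` with the residual when the geometry
        is infeasible.
        """
        q = np.array(q_guess, dtype=float)
        if not self.constraints:
            return q
        W = np.ones(self.nu) if weights is None else np.asarray(weights, dtype=float)
        last = np.inf
        for _ in range(maxiter):
            err = self.constraint_error(q)
            resid = np.abs(err).max()
            if resid <= tol:
                return q
            G = self.constraint_jacobian(q)
            GW = G / W  # G @ W^-1 (diagonal)
            A = GW @ G.T
            try:
                lam = np.linalg.solve(A, -err)
            except np.linalg.LinAlgError as exc:
                raise AssemblyError(
                    f"assembly failed: singular constraint system ({exc})", resid
                ) from exc
            du = (G.T @ lam) / W
            # limit aggressive steps far from the manifold
            step = np.linalg.norm(du)
            if step > 0.5:
                du *= 0.5 / step
            iq = iu = 0
            for j, qs, us in self._iter_slices():
                q[qs] = q[qs] + j.mobilizer.N(q[qs]) @ du[us]
                iq, iu = qs.stop, us.stop
            if resid > 10 * last and resid > 1e-3:
                break
            last = resid
        resid = float(np.abs(self.constraint_error(q)).max())
        if resid <= tol:
            return q
        raise AssemblyError(
            f"assembly did not converge: residual {resid:.3e} m "
            "(infeasible geometry or poor initial guess)",
            resid,
        )

    def project_velocities(self, q, u) -> np.ndarray:
        """Least-change correction of u onto G u = 0."""
        if not self.constraints:
            return u
        G = self.constraint_jacobian(q)
        viol = G @ u
        lam = np.linalg.solve(G @ G.T, viol)
        return u - G.T @ lam

    # --------------------------------------------------------------- dynamics
    def _spatial_inertia_terms(self, kin, u=None):
        """Per-body (Jw, Jc, I_ground, omega, a_com_bias, alpha_bias) lists."""
        out = []
        for body in self.bodies.values():
            if body.name == self.root.name:
                continue
            bk = kin[body.name]
            Rb = bk.X.R
            I_G = Rb @ body.inertia @ Rb.T
            Jc = self._point_jacobian(bk, body.com)
            ac_bias = self._point_bias_accel(bk, body.com)
            out.append((body, bk, bk.J[:3], Jc, I_G, ac_bias))
        return out

    def mass_matrix(self, q) -> np.ndarray:
        kin = self._kinematics(q, want_jacobian=True)
        M = np.zeros((self.nu, self.nu))
        for body, bk, Jw, Jc, I_G, _ in self._spatial_inertia_terms(kin):
            M += Jw.T @ I_G @ Jw + body.mass * (Jc.T @ Jc)
        return M

    def _generalized_forces(self, kin, u, mobility_forces, external_wrenches,
                            include_gravity=True):
        f_app = np.zeros(self.nu)
        f_inert = np.zeros(self.nu)
        for body, bk, Jw, Jc, I_G, ac_bias in self._spatial_inertia_terms(kin):
            if include_gravity:
                f_app += body.mass * (Jc.T @ self.gravity)
            f_inert += Jc.T @ (body.mass * ac_bias)
            f_inert += Jw.T @ (I_G @ bk.alpha_bias + np.cross(bk.w, I_G @ bk.w))
        if mobility_forces is not None:
            f_app = f_app + np.asarray(mobility_forces, dtype=float)
        if external_wrenches:
            for name, (torque, force, station) in external_wrenches.items():
                bk = kin[name]
                f_app += bk.J[:3].T @ np.asarray(torque, dtype=float)
                f_app += self._point_jacobian(bk, station).T @ np.asarray(
                    force, dtype=float
                )
        return f_app, f_inert

    def solve_dynamics(
        self,
        q,
        u,
        mobility_forces=None,
        include_gravity=True,
    ) -> SystemDynamics:
        """Solve the constrained equations of motion for udot and multipliers.

        ``mobility_forces`` are applied generalized forces conjugate to u
        (torques, since every mobility here is angular); gravity is applied
        at each COM unless disabled.
        """
        q = np.asarray(q, dtype=float)
        u = np.asarray(u, dtype=float)
        kin = self._kinematics(q, u, want_jacobian=True)
        M = np.zeros((self.nu, self.nu))
        for body, bk, Jw, Jc, I_G, _ in self._spatial_inertia_terms(kin):
            M += Jw.T @ I_G @ Jw + body.mass * (Jc.T @ Jc)
        f_app, f_inert = self._generalized_forces(kin, u, mobility_forces, None,
                                                  include_gravity)
        m = self.n_constraint_equations
        if m:
            G, b = self._constraint_matrices(kin)
            if np.linalg.matrix_rank(G, tol=1e-10) < m:
                raise RedundantConstraintError(
                    "constraint Jacobian is rank deficient"
                )
            KKT = np.block([[M, G.T], [G, np.zeros((m, m))]])
            rhs = np.concatenate([f_app - f_inert, b])
            sol = np.linalg.solve(KKT, rhs)
            udot, lam = sol[: self.nu], sol[self.nu :]
        else:
            G = np.zeros((0, self.nu))
            b = np.zeros(0)
            lam = np.zeros(0)
            udot = np.linalg.solve(M, f_app - f_inert)
        return SystemDynamics(M, G, b, f_app, f_inert, lam, udot)

    def inverse_dynamics(
        self,
        q,
        u,
        udot,
        multipliers=None,
        include_gravity=True,
        constraint_tol=None,
    ) -> np.ndarray:
        """Generalized applied forces producing the given accelerations.

        Returns the actuation f with M udot + f_inertial + G^T lambda =
        f + f_gravity.  With a closed loop, (f, lambda) is a 3-parameter
        family -- the split between actuation and the loop constraint is
        statically indeterminate -- so multipliers may be supplied (e.g.
        from a forward-dynamics solve); by default lambda = 0, attributing
        the entire load to the reported generalized forces.
        """
        q = np.asarray(q, dtype=float)
        u = np.asarray(u, dtype=float)
        udot = np.asarray(udot, dtype=float)
        kin = self._kinematics(q, u, want_jacobian=True)
        M = np.zeros((self.nu, self.nu))
        for body, bk, Jw, Jc, I_G, _ in self._spatial_inertia_terms(kin):
            M += Jw.T @ I_G @ Jw + body.mass * (Jc.T @ Jc)
        f_grav, f_inert = self._generalized_forces(kin, u, None, None,
                                                   include_gravity)
        f = M @ udot + f_inert - f_grav
        if self.constraints:
            G, b = self._constraint_matrices(kin)
            if constraint_tol is not None:
                pos_resid = float(np.abs(self.constraint_error(q)).max())
                if pos_resid > constraint_tol:
                    raise ValueError(
                        f"constraint-inconsistent input: position residual "
                        f"{pos_resid:.3e} m exceeds {constraint_tol:.3e} m"
                    )
            if multipliers is not None:
                f = f + G.T @ np.asarray(multipliers, dtype=float)
        return f

    # --------------------------------------------------------------- energies
    def kinetic_energy(self, q, u) -> float:
        return 0.5 * float(np.asarray(u) @ self.mass_matrix(q) @ np.asarray(u))

    def potential_energy(self, q) -> float:
        """Gravitational potential, zero at the ground origin."""
        X = self.forward_kinematics(q)
        V = 0.0
        for body in self.bodies.values():
            if body.name == self.root.name:
                continue
            p_com = X[body.name].apply(body.com)
            V -= body.mass * float(self.gravity @ p_com)
        return V

    def gravity_generalized_forces(self, q) -> np.ndarray:
        kin = self._kinematics(q, want_jacobian=True)
        f = np.zeros(self.nu)
        for body, bk, Jw, Jc, I_G, _ in self._spatial_inertia_terms(kin):
            f += body.mass * (Jc.T @ self.gravity)
        return f

    # --------------------------------------------------------- reaction loads
    def reaction_loads(
        self, q, u, udot, multipliers=None, include_gravity=True
    ) -> dict:
        """Interbody spatial loads by distal-to-proximal Newton-Euler balance.

        For each joint, the returned load is the total wrench the parent
        applies to the child through the mobilizer, expressed in ground
        about the joint M-frame origin; loop-constraint forces enter as
        known applied forces (+/- lambda at the two stations).
        """
        q = np.asarray(q, dtype=float)
        u = np.asarray(u, dtype=float)
        udot = np.asarray(udot, dtype=float)
        kin = self._kinematics(q, u, want_jacobian=True)
        lam = (
            np.zeros(self.n_constraint_equations)
            if multipliers is None
            else np.asarray(multipliers, dtype=float)
        )

        # constraint forces on each body: -lambda at station_a, +lambda at b
        con_wrench = {name: [] for name in self.bodies}
        for i, c in enumerate(self.constraints):
            li = lam[3 * i : 3 * i + 3]
            pa, _ = self._point_state(kin[c.body_a], c.station_a)
            pb, _ = self._point_state(kin[c.body_b], c.station_b)
            con_wrench[c.body_a].append((-li, pa))
            con_wrench[c.body_b].append((+li, pb))

        children = {name: [] for name in self.bodies}
        for j in self.joints:
            children[j.parent].append(j)

        loads: dict[str, ReactionLoad] = {}

        def visit(joint: Joint) -> ReactionLoad:
            body = self.bodies[joint.child]
            bk = kin[joint.child]
            p_ref = bk.p_M  # express moments about the joint M origin
            # dynamic wrench
            alpha = bk.J[:3] @ udot + bk.alpha_bias
            a_com = (
                self._point_jacobian(bk, body.com) @ udot
                + self._point_bias_accel(bk, body.com)
            )
            Rb = bk.X.R
            I_G = Rb @ body.inertia @ Rb.T
            p_com, _ = self._point_state(bk, body.com)
            F_dyn = body.mass * a_com
            T_dyn = I_G @ alpha + np.cross(bk.w, I_G @ bk.w) + np.cross(
                p_com - p_ref, F_dyn
            )
            # applied forces
            F_app = np.zeros(3)
            T_app = np.zeros(3)
            if include_gravity and body.mass:
                Fg = body.mass * self.gravity
                F_app += Fg
                T_app += np.cross(p_com - p_ref, Fg)
            for fvec, ppt in con_wrench[joint.child]:
                F_app += fvec
                T_app += np.cross(ppt - p_ref, fvec)
            # wrenches from outboard joints (children pull back with -reaction)
            F_out = np.zeros(3)
            T_out = np.zeros(3)
            for cj in children[joint.child]:
                rl = loads[cj.name]
                F_out += -rl.force
                T_out += -(rl.moment + np.cross(rl.point - p_ref, rl.force))
            force = F_dyn - F_app - F_out
            moment = T_dyn - T_app - T_out
            rl = ReactionLoad(joint.name, moment, force, p_ref.copy())
            loads[joint.name] = rl
            return rl

        # distal-first traversal
        for j in reversed(self.joints):
            visit(j)
        return loads
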