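import numpy as np
import pytest

from scapmob.mobilizers import PinMobilizer
from scapmob.multibody import (
    AssemblyError,
    Body,
    Joint,
    ModelTree,
    PointConstraint,
)
from scapmob.spatial import Transform

from conftest import make_pendulum


def random_assembled_state(model, rng, scale=0.1):
    q = model.assemble(model.default_q + rng.uniform(-scale, scale, model.nq))
    u = model.project_velocities(q, rng.standard_normal(model.nu))
    return q, u


class TestForwardKinematics:
    def test_default_pose_scapula_on_ellipsoid(self, model):
        """At the default pose the scapulothoracic joint origin lies on the
        thoracic ellipsoid (the motion-manifold property)."""
        surf = model.meta["surface"]
        kin = model._kinematics(model.default_q)
        p_M_thorax = surf.frame.inverse().apply(kin["scapula"].p_M)
        assert abs(surf.implicit(p_M_thorax) - 1.0) < 1e-12

    def test_subtree_locality(self, model):
        q = model.default_q.copy()
        X0 = model.forward_kinematics(q)
        q2 = q.copy()
        q2[model.q_slices()["glenohumeral"]] += 0.2  # distal coordinate
        X1 = model.forward_kinematics(q2)
        for name in ("thorax", "clavicle", "scapula"):
            assert X0[name].almost_equal(X1[name], tol=1e-14)
        assert not X0["humerus"].almost_equal(X1["humerus"], tol=1e-6)

    def test_marker_positions_vs_chain_multiplication_oracle(self, model):
        """Marker world positions agree with an explicit per-body chain of
        transform compositions built outside the recursion."""
        rng = np.random.default_rng(7)
        q = model.default_q + rng.uniform(-0.2, 0.2, model.nq)
        pos = model.marker_positions(q)
        qsl = model.q_slices()
        # explicit chains
        chains = {
            "thorax": [],
            "clavicle": [("sternoclavicular", "thorax")],
            "scapula": [("scapulothoracic", "thorax")],
            "humerus": [("scapulothoracic", "thorax"), ("glenohumeral", "scapula")],
        }
        for body_name, joints in chains.items():
            X = Transform.identity()
            for jname, _parent in joints:
                j = model.joint(jname)
                X = X @ j.X_PF @ j.mobilizer.transform(q[qsl[jname]]) @ j.X_BM.inverse()
            body = model.bodies[body_name]
            for mname, station in body.markers.items():
                assert np.abs(X.apply(station) - pos[mname]).max() < 1e-12


class TestSolveDynamics:
    def test_rest_no_forces_no_motion(self, model):
        import copy

        m = copy.deepcopy(model)
        m.gravity = np.zeros(3)
        dyn = m.solve_dynamics(m.default_q, np.zeros(m.nu))
        assert np.abs(dyn.udot).max() < 1e-9
        assert np.abs(dyn.multipliers).max() < 1e-9

    def test_pendulum_closed_form(self, pendulum):
        m_, lc, Ic = 1.7, 0.23, 0.02
        I0 = Ic + m_ * lc * lc
        for th in (0.3, -1.1, 2.0):
            dyn = pendulum.solve_dynamics(np.array([th]), np.zeros(1))
            assert dyn.udot[0] == pytest.approx(-m_ * 9.81 * lc * np.sin(th) / I0,
                                                abs=1e-12)

    def test_matches_dense_lagrange_oracle(self, model):
        """KKT solution equals an independent Schur-complement solve."""
        rng = np.random.default_rng(17)
        q, u = random_assembled_state(model, rng)
        tau = rng.standard_normal(model.nu)
        dyn = model.solve_dynamics(q, u, mobility_forces=tau)
        Minv = np.linalg.inv(dyn.M)
        rhs = dyn.f_applied - dyn.f_inertial
        S = dyn.G @ Minv @ dyn.G.T
        lam = np.linalg.solve(S, dyn.G @ Minv @ rhs - dyn.b)
        udot = Minv @ (rhs - dyn.G.T @ lam)
        assert np.abs(udot - dyn.udot).max() < 1e-8
        assert np.abs(lam - dyn.multipliers).max() < 1e-8

    def test_equation_residuals(self, model):
        rng = np.random.default_rng(18)
        q, u = random_assembled_state(model, rng)
        dyn = model.solve_dynamics(q, u)
        r1, r2 = dyn.residuals()
        scale = max(1.0, np.abs(dyn.f_applied).max())
        assert np.abs(r1).max() / scale < 1e-9
        assert np.abs(r2).max() < 1e-9

    def test_mass_matrix_spd_100_configurations(self, model):
        rng = np.random.default_rng(19)
        for _ in range(100):
            q = model.default_q + rng.uniform(-0.3, 0.3, model.nq)
            M = model.mass_matrix(q)
            assert np.abs(M - M.T).max() < 1e-12
            assert np.linalg.eigvalsh(M)[0] > 0

    def test_redundant_constraints_reported(self, model):
        import copy

        m = copy.deepcopy(model)
        m.add_constraint(copy.deepcopy(m.constraints[0]))  # duplicate -> rank deficient
        from scapmob.multibody import RedundantConstraintError

        with pytest.raises(RedundantConstraintError):
            m.solve_dynamics(m.default_q, np.zeros(m.nu))


class TestInverseDynamics:
    def test_zero_gravity_rest_gives_zero_forces(self, pendulum):
        import copy

        m = copy.deepcopy(pendulum)
        m.gravity = np.zeros(3)
        f = m.inverse_dynamics(np.array([0.4]), np.zeros(1), np.zeros(1))
        assert np.abs(f).max() < 1e-14

    def test_static_forces_equal_potential_gradient(self, model):
        """At rest, applied generalized forces equal N^T dV/dq (finite
        difference of the gravitational potential -- independent oracle)."""
        rng = np.random.default_rng(23)
        q, _ = random_assembled_state(model, rng, scale=0.05)
        f = model.inverse_dynamics(q, np.zeros(model.nu), np.zeros(model.nu))
        dV = np.zeros(model.nq)
        for i in range(model.nq):
            e = np.zeros(model.nq)
            e[i] = 1e-6
            dV[i] = (model.potential_energy(q + e) - model.potential_energy(q - e)) / 2e-6
        Nt = np.zeros((model.nu, model.nq))
        for j, qs, us in model._iter_slices():
            Nt[us, qs] = j.mobilizer.N(q[qs]).T
        assert np.abs(f - Nt @ dV).max() < 1e-6

    def test_fd_id_round_trip_constrained(self, model):
        """Forward dynamics under f, then ID with the solved multipliers,
        recovers f exactly (the multiplier resolves the loop-closure
        indeterminacy)."""
        rng = np.random.default_rng(29)
        for _ in range(10):
            q, u = random_assembled_state(model, rng)
            tau = rng.standard_normal(model.nu)
            dyn = model.solve_dynamics(q, u, mobility_forces=tau)
            f = model.inverse_dynamics(q, u, dyn.udot, multipliers=dyn.multipliers)
            assert np.abs(f - tau).max() < 1e-6

    def test_fd_id_round_trip_unconstrained(self, pendulum):
        rng = np.random.default_rng(31)
        for _ in range(10):
            q = rng.uniform(-2, 2, 1)
            u = rng.standard_normal(1)
            tau = rng.standard_normal(1)
            dyn = pendulum.solve_dynamics(q, u, mobility_forces=tau)
            f = pendulum.inverse_dynamics(q, u, dyn.udot)
            assert np.abs(f - tau).max() < 1e-10

    def test_constraint_inconsistency_reported(self, model):
        q_bad = model.default_q + 0.2  # far off the AC manifold
        with pytest.raises(ValueError, match="constraint-inconsistent"):
            model.inverse_dynamics(
                q_bad, np.zeros(model.nu), np.zeros(model.nu), constraint_tol=1e-5
            )


class TestReactionLoads:
    def test_zero_gravity_rest_all_zero(self, model):
        import copy

        m = copy.deepcopy(model)
        m.gravity = np.zeros(3)
        loads = m.reaction_loads(m.default_q, np.zeros(m.nu), np.zeros(m.nu),
                                 np.zeros(3))
        for rl in loads.values():
            assert np.abs(rl.force).max() < 1e-12
            assert np.abs(rl.moment).max() < 1e-12

    def test_global_force_balance_under_gravity(self, model):
        """Sum of root-attached reactions equals total (inertial - weight)."""
        rng = np.random.default_rng(37)
        q, u = random_assembled_state(model, rng)
        dyn = model.solve_dynamics(q, u)
        loads = model.reaction_loads(q, u, dyn.udot, dyn.multipliers)
        Fsum = sum(loads[j.name].force for j in model.joints if j.parent == "thorax")
        kin = model._kinematics(q, u, want_jacobian=True)
        expected = np.zeros(3)
        for b in model.bodies.values():
            if b.name == "thorax":
                continue
            bk = kin[b.name]
            a_com = model._point_jacobian(bk, b.com) @ dyn.udot + model._point_bias_accel(
                bk, b.com
            )
            expected += b.mass * (a_com - model.gravity)
        assert np.abs(Fsum - expected).max() < 1e-8

    def test_per_body_newton_euler_balance(self, model):
        """Scapula balance: thoracic reaction + GH reaction + gravity +
        constraint force = mass x COM acceleration (the per-body solve)."""
        rng = np.random.default_rng(41)
        q, u = random_assembled_state(model, rng)
        dyn = model.solve_dynamics(q, u)
        loads = model.reaction_loads(q, u, dyn.udot, dyn.multipliers)
        b = model.bodies["scapula"]
        kin = model._kinematics(q, u, want_jacobian=True)
        bk = kin["scapula"]
        a_com = model._point_jacobian(bk, b.com) @ dyn.udot + model._point_bias_accel(
            bk, b.com
        )
        F = (
            loads["scapulothoracic"].force
            - loads["glenohumeral"].force
            + b.mass * model.gravity
            + dyn.multipliers  # +lambda acts on the scapula (constraint body B)
        )
        assert np.abs(F - b.mass * a_com).max() < 1e-8


class TestAssemble:
    def test_consistent_guess_unchanged(self, model):
        q = model.assemble(model.default_q)
        assert np.abs(q - model.default_q).max() < 1e-12

    def test_perturbed_guess_converges_below_tolerance(self, model):
        rng = np.random.default_rng(43)
        for _ in range(10):
            guess = model.default_q + rng.uniform(-np.radians(5), np.radians(5),
                                                  model.nq)
            q = model.assemble(guess, tol=1e-9)
            assert np.abs(model.constraint_error(q)).max() <= 1e-5  # 0.01 mm

    def test_infeasible_geometry_fails_explicitly(self, model):
        import copy

        m = copy.deepcopy(model)
        for c in m.constraints:
            c.station_a = c.station_a * 10.0  # clavicle far too long to close
        with pytest.raises(AssemblyError) as err:
            m.assemble(m.default_q)
        assert err.value.residual > 1e-5


class TestConservation:
    def test_axial_momentum_conserved_without_gravity(self):
        """A gravity-free pin chain conserves angular momentum about the
        base axis while exchanging it internally."""
        from scapmob.dynamics_analysis import simulate_passive_swing

        ground = Body("ground")
        m = ModelTree(ground, gravity=(0, 0, 0))
        link1 = Body("l1", mass=1.0, inertia=np.diag([0.02, 0.02, 0.01]),
                     com=(0, -0.15, 0))
        m.add_body(link1, Joint("p1", "ground", "l1", PinMobilizer((0, 0, 1))))
        link2 = Body("l2", mass=0.8, inertia=np.diag([0.01, 0.01, 0.005]),
                     com=(0, -0.1, 0))
        m.add_body(
            link2,
            Joint("p2", "l1", "l2", PinMobilizer((0, 0, 1)),
                  X_PF=Transform.from_translation((0, -0.3, 0))),
        )

        def Lz(q, u):
            kin = m._kinematics(q, u, want_jacobian=True)
            total = 0.0
            for b in (link1, link2):
                bk = kin[b.name]
                p_com, _ = m._point_state(bk, b.com)
                v_com = m._point_jacobian(bk, b.com) @ u
                I_G = bk.X.R @ b.inertia @ bk.X.R.T
                total += (I_G @ bk.w)[2] + b.mass * np.cross(p_com, v_com)[2]
            return total

        q0, u0 = np.array([0.3, -0.8]), np.array([1.0, -2.0])
        res = simulate_passive_swing(m, q0, u0=u0, duration=1.0, accuracy=1e-6)
        L = [Lz(q, u) for q, u in zip(res.coordinates, res.speeds)]
        assert np.abs(np.array(L) - L[0]).max() < 1e-5 * max(1.0, abs(L[0]))

    def test_fd_id_round_trip_random_states(self, model):
        rng = np.random.default_rng(47)
        for _ in range(5):
            q, u = random_assembled_state(model, rng)
            tau = rng.standard_normal(model.nu)
            dyn = model.solve_dynamics(q, u, mobility_forces=tau)
            f = model.inverse_dynamics(q, u, dyn.udot, multipliers=dyn.multipliers)
            assert np.abs(f - tau).max() < 1e-6
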