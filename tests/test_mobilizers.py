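import numpy as np
import pytest

from scapmob.mobilizers import (
    ElevationSingularityError,
    EllipsoidMobilizer,
    EllipsoidSurface,
    GimbalMobilizer,
    PinMobilizer,
    ScapulothoracicMobilizer,
    UniversalMobilizer,
    coupling_N,
    ellipsoid_H,
    ellipsoid_Hdot,
    ellipsoid_translation,
    surface_normal,
)

SURF = EllipsoidSurface(radii=(0.07, 0.10, 0.12))


def spatial_velocity_fd(mob, q, u, dt=1e-7):
    """Finite-difference oracle for the spatial velocity of M in F."""
    q2 = q + mob.qdot(q, u) * dt
    X1, X2 = mob.transform(q), mob.transform(q2)
    Om = (X2.R - X1.R) / dt @ X1.R.T
    om = np.array([Om[2, 1], Om[0, 2], Om[1, 0]])
    return np.concatenate([om, (X2.p - X1.p) / dt])


ALL_MOBILIZERS = [
    PinMobilizer((0.3, 0.5, 0.81)),
    UniversalMobilizer(),
    GimbalMobilizer("YXY"),
    GimbalMobilizer("YXZ"),
    EllipsoidMobilizer(SURF),
    ScapulothoracicMobilizer(SURF),
    ScapulothoracicMobilizer(SURF, winging_axis=(0.2, 0.9, 0.1)),
]


@pytest.mark.parametrize("mob", ALL_MOBILIZERS, ids=lambda m: type(m).__name__)
class TestMobilizerContract:
    """Every mobilizer must keep X, H, Hdot and N mutually consistent."""

    def test_H_matches_finite_difference_of_X(self, mob):
        rng = np.random.default_rng(11)
        for _ in range(100):
            q = rng.uniform(-0.9, 0.9, mob.nq)
            u = rng.standard_normal(mob.nu)
            V = spatial_velocity_fd(mob, q, u)
            assert np.abs(V - mob.H(q) @ u).max() < 1e-6

    def test_Hdot_matches_finite_difference_of_H(self, mob):
        rng = np.random.default_rng(12)
        for _ in range(100):
            q = rng.uniform(-0.9, 0.9, mob.nq)
            u = rng.standard_normal(mob.nu)
            dt = 1e-6
            Hfd = (mob.H(q + mob.qdot(q, u) * dt) - mob.H(q)) / dt
            assert np.abs(Hfd - mob.Hdot(q, u)).max() < 1e-5

    def test_Hdot_zero_at_rest(self, mob):
        q = np.full(mob.nq, 0.3)
        assert np.allclose(mob.Hdot(q, np.zeros(mob.nu)), 0.0)

    def test_rate_conversions_invert(self, mob):
        rng = np.random.default_rng(13)
        q = rng.uniform(-0.8, 0.8, mob.nq)
        u = rng.standard_normal(mob.nu)
        assert np.allclose(mob.u_from_qdot(q, mob.qdot(q, u)), u, atol=1e-12)


class TestEllipsoidTranslation:
    def test_zero_pose_sits_at_depth_pole(self):
        assert np.allclose(
            ellipsoid_translation([0.0, 0.0, 0.4], SURF), [0, 0, 0.12]
        )

    def test_elevation_limit_reaches_height_pole(self):
        p = ellipsoid_translation([0.0, np.pi / 2, 0.0], SURF)
        assert np.allclose(p, [0.07, 0, 0], atol=1e-15)

    def test_point_satisfies_implicit_surface_equation(self):
        # independent oracle: substitute into (x/h)^2 + (y/w)^2 + (z/d)^2
        q = np.array([np.radians(30), np.radians(45), 1.234])
        p = ellipsoid_translation(q, SURF)
        assert abs(SURF.implicit(p) - 1.0) < 1e-12

    def test_on_surface_for_1000_random_q(self):
        rng = np.random.default_rng(21)
        for _ in range(1000):
            q = rng.uniform(-1.4, 1.4, 3)
            assert abs(SURF.implicit(ellipsoid_translation(q, SURF)) - 1.0) < 1e-12

    def test_normal_is_unit_and_has_stated_components(self):
        q = np.array([0.5, -0.3, 0.9])
        n = surface_normal(q)
        assert abs(np.linalg.norm(n) - 1.0) < 1e-15
        t1, t2 = q[0], q[1]
        expected = [
            np.sin(t2),
            -np.sin(t1) * np.cos(t2),
            np.cos(t1) * np.cos(t2),
        ]
        assert np.allclose(n, expected)


class TestEllipsoidH:
    def test_angular_block_is_identity(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            H = ellipsoid_H(rng.uniform(-1, 1, 3), SURF)
            assert np.allclose(H[:3], np.eye(3))

    def test_sphere_limit_matches_tangent_velocity(self):
        """For h=w=d=r the linear rows reproduce r*(u x n) exactly."""
        r = 0.09
        sphere = EllipsoidSurface(radii=(r, r, r))
        rng = np.random.default_rng(6)
        for _ in range(50):
            q = rng.uniform(-1, 1, 3)
            u = rng.standard_normal(3)
            v = ellipsoid_H(q, sphere)[3:] @ u
            assert np.allclose(v, r * np.cross(u, surface_normal(q)), atol=1e-14)

    def test_acceleration_consistency_along_prescribed_motion(self):
        """H udot + Hdot u matches the second finite difference of position."""
        mob = EllipsoidMobilizer(SURF)

        def q_of_t(t):  # smooth prescribed coordinates
            return np.array([0.4 * np.sin(t), 0.3 * np.cos(1.3 * t), 0.2 * t])

        t0, dt = 0.37, 1e-5
        qm, q, qp = (q_of_t(t0 + k * dt) for k in (-1, 0, 1))
        u = mob.u_from_qdot(q, (qp - qm) / (2 * dt))
        um = mob.u_from_qdot(qm, (q_of_t(t0) - q_of_t(t0 - 2 * dt)) / (2 * dt))
        up = mob.u_from_qdot(qp, (q_of_t(t0 + 2 * dt) - q_of_t(t0)) / (2 * dt))
        udot = (up - um) / (2 * dt)
        a_fd = (mob.transform(qp).p - 2 * mob.transform(q).p + mob.transform(qm).p) / dt**2
        a = (mob.H(q) @ udot + mob.Hdot(q, u) @ u)[3:]
        assert np.abs(a - a_fd).max() < 1e-4


class TestCouplingN:
    def test_identity_at_zero_pose(self):
        assert np.allclose(coupling_N(np.zeros(3)), np.eye(3))

    def test_euler_rates_match_finite_difference(self):
        """Integrating qdot = N u tracks the orientation: dq/dt from N
        equals the finite difference of the coordinates along the motion."""
        mob = EllipsoidMobilizer(SURF)
        rng = np.random.default_rng(31)
        for _ in range(50):
            q = rng.uniform(-0.9, 0.9, 3)
            u = rng.standard_normal(3)
            dt = 1e-7
            # independent route: perturb the rotation by the angular velocity
            from scipy.spatial.transform import Rotation as SR

            R = mob.transform(q).R
            R2 = SR.from_rotvec(u * dt).as_matrix() @ R
            q2 = SR.from_matrix(R2).as_euler("XYZ")
            qdot_fd = (q2 - q) / dt
            assert np.abs(qdot_fd - coupling_N(q) @ u).max() < 1e-6

    def test_singularity_at_90_deg_elevation(self):
        with pytest.raises(ElevationSingularityError):
            coupling_N([0.2, np.pi / 2, 0.1])
        # and the 1/cos terms grow unboundedly on approach
        n1 = np.abs(coupling_N([0.2, 1.55, 0.0])).max()
        n2 = np.abs(coupling_N([0.2, 1.5705, 0.0])).max()
        assert n2 > n1 > 10


class TestScapulothoracicJoint:
    def test_exposes_four_coordinates(self):
        mob = ScapulothoracicMobilizer(SURF)
        assert mob.nq == mob.nu == 4

    def test_zero_pose(self):
        X = ScapulothoracicMobilizer(SURF).transform(np.zeros(4))
        assert np.allclose(X.p, [0, 0, SURF.radii[2]])
        assert np.allclose(X.R, np.eye(3))

    def test_winging_rotates_without_translating(self):
        mob = ScapulothoracicMobilizer(SURF)
        X0 = mob.transform(np.zeros(4))
        Xw = mob.transform([0, 0, 0, np.radians(10)])
        assert np.allclose(Xw.p, X0.p)
        from scapmob.spatial import axis_rotation

        assert np.allclose(Xw.R, X0.R @ axis_rotation("Y", np.radians(10)), atol=1e-14)

    def test_coordinate_extraction_round_trip(self):
        for axis in [(0, 1, 0), (0.2, 0.9, 0.1)]:
            mob = ScapulothoracicMobilizer(SURF, winging_axis=axis)
            rng = np.random.default_rng(41)
            for _ in range(25):
                q = rng.uniform(-1.2, 1.2, 4)
                X = mob.transform(q)
                q2 = mob.coords_from_transform(X)
                assert mob.transform(q2).almost_equal(X, tol=1e-9)

    def test_off_surface_transform_rejected(self):
        mob = ScapulothoracicMobilizer(SURF)
        X = mob.transform(np.zeros(4))
        from scapmob.spatial import Transform

        bad = Transform(X.R, X.p * 1.1)
        with pytest.raises(ValueError):
            mob.coords_from_transform(bad)


def test_hdot_vanishes_when_u_zero_ellipsoid():
    q = np.array([0.4, -0.2, 0.7])
    assert np.allclose(ellipsoid_Hdot(q, np.zeros(3), SURF), 0.0)
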