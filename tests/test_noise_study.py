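import numpy as np
import pytest
from scipy.stats import spearmanr

from scapmob.ik import MarkerTrajectory
from scapmob.noise_study import (
    ANGLE_NAMES,
    NoiseSpec,
    add_noise,
    direct_isb_angles,
    mean_rmse_by_level,
    model_isb_angles,
    percent_reduction,
    run_noise_experiment,
    synthesize_motion,
    threshold_crossing,
)
from scapmob.spatial import random_rotation


class TestSynthesizeMotion:
    def test_flexion_upward_rotation_peaks_mid_trial(self, model, flexion):
        motion, _ = flexion
        upr = motion.coordinate("st_upward_rotation")
        peak = np.argmax(upr)
        assert abs(motion.times[peak] - motion.peak_time) < 0.1
        # monotone rise to the peak and return
        assert np.all(np.diff(upr[: peak + 1]) >= -1e-9)
        assert np.all(np.diff(upr[peak:]) <= 1e-9)

    def test_starts_and_ends_neutral_and_static(self, model, flexion):
        motion, _ = flexion
        assert np.abs(motion.coordinates[0] - model.default_q).max() < 1e-9
        assert np.abs(motion.coordinates[-1] - model.default_q).max() < 1e-9
        # static: first finite difference ~0 at the ends
        v0 = motion.coordinates[1] - motion.coordinates[0]
        assert np.abs(v0).max() < 1e-3

    def test_constraint_satisfied_every_frame(self, model, flexion):
        motion, _ = flexion
        for q in motion.coordinates[::20]:
            assert np.abs(model.constraint_error(q)).max() < 1e-8

    def test_markers_round_trip_through_ik(self, model, flexion):
        from scapmob.ik import solve_trial

        motion, traj = flexion
        sub = MarkerTrajectory(traj.names, traj.positions[::20], traj.rate / 20)
        res = solve_trial(model, sub)
        assert np.abs(res.coordinates - motion.coordinates[::20]).max() < 1e-6

    def test_unknown_task_rejected(self, model):
        with pytest.raises(ValueError):
            synthesize_motion(model, "shrug")


class TestAddNoise:
    def _tiny_traj(self, n=121, m=4, rate=120.0):
        rng = np.random.default_rng(0)
        return MarkerTrajectory(
            [f"M{i}" for i in range(m)], rng.normal(size=(n, m, 3)), rate
        )

    def test_zero_level_zero_sd_is_identity(self):
        traj = self._tiny_traj()
        spec = NoiseSpec(level_mm=0.0, peak_time=0.5, sd_mm=0.0, seed=1)
        out = add_noise(traj, spec)
        assert np.array_equal(out.positions, traj.positions)

    def test_determinism_contract(self):
        traj = self._tiny_traj()
        spec = NoiseSpec(level_mm=20.0, peak_time=0.5, seed=7)
        a = add_noise(traj, spec)
        b = add_noise(traj, spec)
        assert np.array_equal(a.positions, b.positions)
        c = add_noise(traj, NoiseSpec(level_mm=20.0, peak_time=0.5, seed=8))
        assert not np.array_equal(a.positions, c.positions)

    def test_bias_envelope_monte_carlo(self):
        """Mean offset magnitude ~ level at the peak, ~0 at the ends
        (averaged over 500 trials)."""
        traj = self._tiny_traj()
        peak = traj.times[len(traj.times) // 2]
        mags_peak, mags_end = [], []
        for seed in range(500):
            spec = NoiseSpec(level_mm=20.0, peak_time=peak, sd_mm=0.0, seed=seed)
            out = add_noise(traj, spec)
            d = out.positions - traj.positions
            mags_peak.append(np.linalg.norm(d[len(traj.times) // 2], axis=1).mean())
            mags_end.append(np.linalg.norm(d[0], axis=1).mean())
        assert np.mean(mags_peak) == pytest.approx(20e-3, rel=0.02)
        assert np.mean(mags_end) < 0.5e-3  # envelope ~0 in the neutral posture

    def test_direction_held_constant_within_trial(self):
        traj = self._tiny_traj()
        spec = NoiseSpec(level_mm=30.0, peak_time=0.5, sd_mm=0.0, seed=3)
        d = add_noise(traj, spec).positions - traj.positions
        dirs = d / np.linalg.norm(d, axis=2, keepdims=True)
        assert np.abs(dirs - dirs[:1]).max() < 1e-9

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(level_mm=-1.0, peak_time=0.5)


class TestDirectISBAngles:
    def test_matches_model_angles_on_noise_free_markers(self, model, flexion):
        """The triad construction applied to measured markers equals the
        same construction applied to the model's markers at the same pose
        (rotation-composition oracle)."""
        motion, traj = flexion
        sub = MarkerTrajectory(traj.names, traj.positions[::40], traj.rate)
        ang_direct = direct_isb_angles(sub, cutoff=None)
        ang_model = model_isb_angles(model, motion.coordinates[::40])
        assert np.abs(ang_direct - ang_model).max() < 1e-9

    def test_rigid_translation_invariance(self, model, flexion):
        _, traj = flexion
        sub = MarkerTrajectory(traj.names, traj.positions[:5] + [0.3, -0.1, 2.0],
                               traj.rate)
        base = MarkerTrajectory(traj.names, traj.positions[:5], traj.rate)
        assert np.allclose(
            direct_isb_angles(sub, None), direct_isb_angles(base, None), atol=1e-12
        )

    def test_whole_cloud_rotation_invariance(self, model, flexion):
        _, traj = flexion
        R = random_rotation(np.random.default_rng(4))
        rot = MarkerTrajectory(traj.names, traj.positions[:5] @ R.T, traj.rate)
        base = MarkerTrajectory(traj.names, traj.positions[:5], traj.rate)
        assert np.allclose(
            direct_isb_angles(rot, None), direct_isb_angles(base, None), atol=1e-9
        )

    def test_collinear_triad_reported(self):
        n, names = 3, ["AA", "TS", "AI", "IJ", "C7", "T8"]
        pos = np.zeros((n, 6, 3))
        pos[:, 0] = [0, 0, 0.1]
        pos[:, 1] = [0, 0, 0.0]
        pos[:, 2] = [0, 0, -0.1]  # scapula triad collinear
        pos[:, 3] = [0.07, 0, 0]
        pos[:, 4] = [-0.07, 0.03, 0]
        pos[:, 5] = [-0.1, -0.18, 0]
        from scapmob.isb import DegenerateTriadError

        with pytest.raises(DegenerateTriadError):
            direct_isb_angles(MarkerTrajectory(names, pos, 120.0), None)


class TestExperimentTable:
    """Statistical structure of the scaled-down noise experiment."""

    def test_method_ordering_at_every_level(self, noise_table):
        direct = mean_rmse_by_level(noise_table, "direct")
        euler = mean_rmse_by_level(noise_table, "model_euler")
        coords = mean_rmse_by_level(noise_table, "joint_coords")
        assert np.all(euler.values < direct.values)
        assert np.all(coords.values <= euler.values)

    def test_rmse_monotone_in_level(self, noise_table):
        for method in ("direct", "model_euler", "joint_coords"):
            series = mean_rmse_by_level(noise_table, method)
            rho = spearmanr(series.index, series.values).statistic
            assert rho > 0.9

    def test_table_shape(self, noise_table):
        levels = noise_table.level_mm.unique()
        assert len(levels) == 8
        per_level = noise_table.groupby("level_mm").size()
        assert np.all(per_level.values == 3 + 3 + 4)  # angles + angles + coords

    def test_zero_level_rmse_near_zero(self, model, flexion):
        motion, traj = flexion
        df = run_noise_experiment(model, motion, traj, [0], trials=1, seed=0)
        assert df.rmse_mean_deg.max() < 0.05  # only filter-edge artifacts
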