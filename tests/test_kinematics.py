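"""Chain model, registration, FK, IK and marker Procrustes."""

import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes

from imugait import kinematics as kin
from imugait import rotations as rot
from imugait.imu_fusion import OrientationTrack


class TestChainModel:
    def test_dof_structure(self, model2, model1):
        assert model2.n_dofs == 18 and model1.n_dofs == 16
        assert len(model2.analysis_dofs) == 12
        assert "ankle_r_AA" in model2.dof_labels
        assert "ankle_r_AA" not in model1.dof_labels

    def test_invalid_ankle_mode(self):
        with pytest.raises(ValueError):
            kin.ChainModel.default("3dof")


class TestSensorToModelFrame:
    def test_identity_maps_to_composite(self):
        out = kin.sensor_to_model_frame(rot.qidentity())
        # oracle: product of the three rotation matrices in applied order
        mx = rot.to_matrix(rot.from_axis_angle([1, 0, 0], np.pi))
        my = rot.to_matrix(rot.from_axis_angle([0, 1, 0], np.pi / 2))
        mz = rot.to_matrix(rot.from_axis_angle([0, 0, 1], -np.pi / 2))
        assert np.abs(rot.to_matrix(out) - mx @ my @ mz).max() < 1e-12

    def test_inverse_composite_roundtrip(self):
        c = kin.sensor_to_model_frame(rot.qidentity())
        assert rot.geodesic_angle(
            kin.sensor_to_model_frame(rot.qconj(c)), rot.qidentity()
        ) < 1e-12

    def test_preserves_relative_angles(self, random_quats):
        q1, q2 = random_quats[:100], random_quats[100:200]
        before = rot.geodesic_angle(q1, q2)
        after = rot.geodesic_angle(
            kin.sensor_to_model_frame(q1), kin.sensor_to_model_frame(q2)
        )
        assert np.abs(before - after).max() < 1e-9


class TestForwardKinematics:
    def test_neutral_pose(self, model2):
        orient, pos = kin.forward_kinematics(model2, np.zeros(model2.n_dofs))
        for q in orient.values():
            assert rot.geodesic_angle(q, rot.qidentity()) < 1e-12
        assert np.allclose(pos["foot_r"], [0.0, -0.09, 0.16])

    def test_single_hip_flexion_propagates(self, model2):
        a = np.zeros(model2.n_dofs)
        a[model2.dof_labels.index("hip_r_FE")] = 30.0
        orient, _ = kin.forward_kinematics(model2, a)
        expect = rot.from_axis_angle([0, 1, 0], np.radians(30))
        for seg in ("femur_r", "tibia_r", "foot_r"):
            rel = rot.qmul(rot.qconj(orient["pelvis"]), orient[seg])
            assert np.degrees(rot.geodesic_angle(rel, expect)) < 1e-9
        # other limbs untouched
        assert rot.geodesic_angle(orient["femur_l"], rot.qidentity()) < 1e-12

    def test_decomposition_roundtrip(self, model2, rng):
        angles = rng.uniform(-40, 40, (50, model2.n_dofs))
        orient, _ = kin.forward_kinematics(model2, angles)
        back = kin._decompose_init(model2, orient)
        assert np.abs(back - angles).max() < 1e-8

    def test_wrong_dof_count(self, model2):
        with pytest.raises(ValueError):
            kin.forward_kinematics(model2, np.zeros(5))


class TestRegistration:
    def test_neutral_sensors_identity_offsets(self, model2):
        neutral = {s: rot.qidentity() for s in model2.segments}
        reg = kin.register(neutral, model2)
        for s in model2.segments:
            assert rot.geodesic_angle(reg.offsets[s], rot.qidentity()) < 1e-9
            assert abs(reg.headings[s]) < 1e-9

    def test_common_heading_removed(self, model2):
        q15 = rot.from_axis_angle([0, 0, 1], np.radians(15))
        neutral = {s: q15 for s in model2.segments}
        reg = kin.register(neutral, model2)
        assert abs(reg.mean_heading - np.radians(15)) < 1e-9
        for s in model2.segments:
            track = OrientationTrack(s, np.zeros(1), q15[None])
            out = reg.apply(track)
            assert rot.geodesic_angle(out.q[0], rot.qidentity()) < 1e-9

    def test_random_mount_offsets_roundtrip(self, model2, rng):
        mounts = {
            s: rot.from_axis_angle(rng.standard_normal(3),
                                   rng.uniform(0, 0.4))
            for s in model2.segments
        }
        neutral = {s: mounts[s] for s in model2.segments}  # q_seg = identity
        reg = kin.register(neutral, model2)
        orient, _ = kin.forward_kinematics(model2, np.zeros(model2.n_dofs))
        for s in model2.segments:
            track = OrientationTrack(s, np.zeros(1), mounts[s][None])
            est = reg.apply(track).q[0]
            assert rot.geodesic_angle(est, orient[s]) < 1e-6

    def test_non_still_window_rejected(self, model2):
        neutral = {s: rot.qidentity() for s in model2.segments}
        gyro = {s: np.full((10, 3), 0.2) for s in model2.segments}
        with pytest.raises(ValueError, match="not still"):
            kin.register(neutral, model2, gyro_windows=gyro)


class TestIkOrientation:
    def test_roundtrip_recovery(self, model2, rng):
        angles = rng.uniform(-35, 35, (200, model2.n_dofs))
        targets, _ = kin.forward_kinematics(model2, angles)
        sol, conv = kin.ik_orientation(model2, targets)
        assert conv.all()
        assert np.abs(sol - angles).max() < 0.01

    def test_objective_nonincreasing_with_noisy_targets(self, model2, rng):
        angles = rng.uniform(-30, 30, (20, model2.n_dofs))
        targets, _ = kin.forward_kinematics(model2, angles)
        noisy = {
            s: rot.qmul(q, rot.from_rotvec(rng.normal(0, 0.02, (20, 3))))
            for s, q in targets.items()
        }
        # forcing a crude start exercises the damped-descent path
        sol, conv = kin.ik_orientation(model2, noisy,
                                       init_deg=np.zeros(model2.n_dofs))
        res0 = sum(
            rot.geodesic_angle(kin.forward_kinematics(
                model2, np.zeros((20, model2.n_dofs)))[0][s], noisy[s]) ** 2
            for s in noisy)
        res1 = sum(
            rot.geodesic_angle(
                kin.forward_kinematics(model2, sol)[0][s], noisy[s]) ** 2
            for s in noisy)
        assert (res1 <= res0 + 1e-12).all()

    def test_unreachable_1dof_matches_grid_search(self, model1):
        a = np.zeros(model1.n_dofs)
        kidx = model1.dof_labels.index("knee_r_FE")
        a[kidx] = 20.0
        targets, _ = kin.forward_kinematics(model1, a)
        # 5 deg of axial rotation the knee cannot reproduce
        targets["tibia_r"] = rot.qmul(
            targets["tibia_r"], rot.from_axis_angle([0, 0, 1], np.radians(5)))
        targets = {s: np.atleast_2d(v) for s, v in targets.items()}
        sol, _ = kin.ik_orientation(model1, targets)
        grid = np.linspace(sol[0, kidx] - 3, sol[0, kidx] + 3, 1201)
        best, best_obj = None, np.inf
        for th in grid:
            trial = sol[0].copy()
            trial[kidx] = th
            o, _ = kin.forward_kinematics(model1, trial)
            obj = sum(float(rot.geodesic_angle(o[s], targets[s][0]) ** 2)
                      for s in targets)
            if obj < best_obj:
                best, best_obj = th, obj
        assert abs(sol[0, kidx] - best) < 0.05

    def test_ankle_mode_ablation(self, model2, model1, rng):
        """Adding the ankle inversion DOF leaves the other joints' IK
        solutions essentially unchanged."""
        # gait-scale postures: large sagittal angles, small frontal and
        # axial components, little ankle inversion
        angles = np.zeros((60, model2.n_dofs))
        for j, d in enumerate(model2.dof_labels):
            if d.endswith("FE"):
                angles[:, j] = rng.uniform(-30, 30, 60)
            elif "ankle" in d:
                angles[:, j] = rng.uniform(-2, 2, 60)
            else:
                angles[:, j] = rng.uniform(-6, 6, 60)
        targets, _ = kin.forward_kinematics(model2, angles)
        sol2, _ = kin.ik_orientation(model2, targets)
        sol1, _ = kin.ik_orientation(model1, targets)
        sagittal = [d for d in model1.dof_labels
                    if d.endswith("FE") and ("hip" in d or "knee" in d)]
        i2 = [model2.dof_labels.index(d) for d in sagittal]
        i1 = [model1.dof_labels.index(d) for d in sagittal]
        assert np.abs(sol2[:, i2] - sol1[:, i1]).max() < 0.5
        # equal-weight least squares lets roughly a third of the
        # unmatchable inversion leak into hip frontal/axial rotation;
        # bounded by the inversion content itself
        others = [d for d in model1.dof_labels if "ankle" not in d]
        j2 = [model2.dof_labels.index(d) for d in others]
        j1 = [model1.dof_labels.index(d) for d in others]
        assert np.abs(sol2[:, j2] - sol1[:, j1]).max() < 1.0


class TestMarkerProcrustes:
    def _traj(self, qs, noise=0.0, rng=None):
        tmpl = {"a": np.zeros(3), "b": np.array([100.0, 0, 0]),
                "c": np.array([0, 100.0, 0]), "d": np.array([30.0, 30, 80])}
        pos = {}
        for mid, p in tmpl.items():
            w = rot.qrotate(qs, p) + np.array([100.0, 50.0, 900.0])
            if noise:
                w = w + rng.normal(0, noise, w.shape)
            pos[mid] = w
        n = len(qs)
        return kin.MarkerTrajectories(
            np.arange(n) / 120.0, pos, {m: "seg" for m in tmpl},
            {"seg": tmpl})

    def test_noiseless_exact(self, random_quats):
        qs = random_quats[:50]
        tracks = kin.segment_orientation_from_markers(self._traj(qs))
        assert rot.geodesic_angle(tracks["seg"].q, qs).max() < 1e-10

    def test_matches_scipy_procrustes(self, random_quats, rng):
        qs = random_quats[:5]
        traj = self._traj(qs, noise=2.0, rng=rng)
        tracks = kin.segment_orientation_from_markers(traj)
        tmpl = np.stack(list(traj.templates["seg"].values()))
        for i in range(5):
            meas = np.stack([traj.positions[m][i] for m in traj.templates["seg"]])
            r_oracle, _ = orthogonal_procrustes(
                tmpl - tmpl.mean(0), meas - meas.mean(0))
            assert np.abs(rot.to_matrix(tracks["seg"].q[i]) - r_oracle.T).max() < 1e-8

    def test_noise_monte_carlo_bound(self, random_quats, rng):
        qs = random_quats[:200]
        tracks = kin.segment_orientation_from_markers(
            self._traj(qs, noise=1.0, rng=rng))
        err = np.degrees(rot.geodesic_angle(tracks["seg"].q, qs))
        assert err.max() < 2.0  # 1 mm noise on a 100 mm cluster

    def test_determinant_plus_one_enforced(self, rng):
        # near-planar cluster + heavy noise tries to flip the solution
        tmpl = {"a": np.zeros(3), "b": np.array([100.0, 0, 0]),
                "c": np.array([0, 100.0, 0]), "d": np.array([50.0, 50.0, 1.0])}
        qs = np.tile(rot.qidentity(), (20, 1))
        pos = {m: rot.qrotate(qs, p) + rng.normal(0, 30.0, (20, 3))
               for m, p in tmpl.items()}
        traj = kin.MarkerTrajectories(np.arange(20) / 120.0, pos,
                                      {m: "seg" for m in tmpl}, {"seg": tmpl})
        tracks = kin.segment_orientation_from_markers(traj)
        det = np.linalg.det(rot.to_matrix(tracks["seg"].q))
        assert np.abs(det - 1).max() < 1e-9

    def test_collinear_cluster_rejected(self):
        tmpl = {"a": np.zeros(3), "b": np.array([50.0, 0, 0]),
                "c": np.array([100.0, 0, 0])}
        qs = np.tile(rot.qidentity(), (5, 1))
        pos = {m: np.tile(p, (5, 1)) for m, p in tmpl.items()}
        traj = kin.MarkerTrajectories(np.arange(5) / 120.0, pos,
                                      {m: "seg" for m in tmpl}, {"seg": tmpl})
        with pytest.raises(ValueError, match="collinear"):
            kin.segment_orientation_from_markers(traj)


class TestPoseOffsetAlignment:
    def _series(self, model, base, n=300):
        t = np.arange(n) / 60.0
        ang = base + np.sin(2 * np.pi * t)[:, None] * np.arange(
            model.n_dofs)[None, :] * 0.1
        return kin.JointAngleSeries(t, ang, model.dof_labels)

    def test_identical_series_zero_offset(self, model2):
        s = self._series(model2, 0.0)
        out = kin.pose_offset_alignment(s, s)
        assert np.abs(out.angles - s.angles).max() < 1e-12

    def test_constant_offset_recovered(self, model2):
        imu = self._series(model2, 0.0)
        ref = kin.JointAngleSeries(imu.t, imu.angles.copy(),
                                   list(imu.labels))
        j = model2.dof_labels.index("hip_r_FE")
        ref.angles[:, j] += 3.0
        out = kin.pose_offset_alignment(ref, imu)
        assert np.abs(out.angles - imu.angles).max() < 1e-9

    def test_offset_leaves_variability_outcomes_unchanged(self, model2):
        from imugait.gait_events import StrideMatrix
        from imugait.variability_metrics import (
            dfa_alpha, lambda_max, mean_sd, rom_per_stride, EmbeddingParams,
            multiscale_sample_entropy,
        )

        rng = np.random.default_rng(8)
        strides = np.sin(2 * np.pi * np.linspace(0, 1, 101))[None, :, None]
        data = strides * (1 + 0.05 * rng.standard_normal((80, 1, 1)))
        cont = data.reshape(-1, 1)
        m0 = StrideMatrix(data, ["x"], cont, 120.0)
        m1 = StrideMatrix(data + 5.0, ["x"], cont + 5.0, 120.0)
        p = EmbeddingParams(n_points=8000, points_per_stride=100)
        assert np.allclose(rom_per_stride(m0)[1], rom_per_stride(m1)[1])
        assert np.allclose(mean_sd(m0), mean_sd(m1))
        assert abs(dfa_alpha(rom_per_stride(m0)[0][:, 0])
                   - dfa_alpha(rom_per_stride(m1)[0][:, 0])) < 1e-12
        assert abs(lambda_max(cont[:, 0], p)
                   - lambda_max(cont[:, 0] + 5.0, p)) < 1e-6
        assert abs(multiscale_sample_entropy(cont[:, 0])
                   - multiscale_sample_entropy(cont[:, 0] + 5.0)) < 1e-9


class TestTableIO:
    def test_quaternion_table_roundtrip(self, tmp_path, random_quats):
        t = np.arange(10) / 60.0
        tracks = {"pelvis": rot.qcanonical(random_quats[:10]),
                  "femur_r": rot.qcanonical(random_quats[10:20])}
        path = tmp_path / "q.sto"
        kin.write_quaternion_table(path, t, tracks)
        t2, back = kin.read_quaternion_table(path)
        assert np.allclose(t, t2)
        for s in tracks:
            assert rot.geodesic_angle(tracks[s], back[s]).max() < 1e-8

    def test_marker_csv_roundtrip(self, tmp_path, rng):
        tmpl = {"m0": np.zeros(3), "m1": np.array([100.0, 0, 0]),
                "m2": np.array([0, 100.0, 0])}
        pos = {m: rng.normal(0, 100, (7, 3)) for m in tmpl}
        traj = kin.MarkerTrajectories(np.arange(7) / 120.0, pos,
                                      {m: "seg" for m in tmpl}, {"seg": tmpl})
        path = tmp_path / "markers.csv"
        kin.write_markers_csv(path, traj)
        back = kin.read_markers_csv(path, traj.marker_segments, traj.templates)
        for m in pos:
            assert np.allclose(back.positions[m], pos[m], atol=1e-9)
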