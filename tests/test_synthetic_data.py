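"""Ground-truth gait generation and sensor simulation."""

import numpy as np
import pytest

from imugait import rotations as rot
from imugait import synthetic_data as syn
from imugait.gait_events import StrideSet, extract_strides
from imugait.kinematics import segment_orientation_from_markers
from imugait.imu_fusion import fuse_trial
from imugait.variability_metrics import dfa_alpha, mean_sd


class TestFgn:
    def test_unit_variance_and_h_half_is_white(self):
        r = np.random.default_rng(0)
        x = syn.fgn(5000, 0.5, r)
        assert abs(x.std() - 1.0) < 0.05
        # lag-1 autocorrelation near zero for H = 0.5
        assert abs(np.corrcoef(x[:-1], x[1:])[0, 1]) < 0.05

    def test_persistence_increases_with_h(self):
        acfs = []
        for h in (0.5, 0.75, 0.9):
            ac = np.mean([
                np.corrcoef(x[:-1], x[1:])[0, 1]
                for x in (syn.fgn(1000, h, np.random.default_rng(s))
                          for s in range(20))
            ])
            acfs.append(ac)
        assert acfs[0] < acfs[1] < acfs[2]

    def test_dfa_recovers_hurst(self):
        for h in (0.5, 0.9):
            alphas = [dfa_alpha(syn.fgn(200, h, np.random.default_rng(s)))
                      for s in range(30)]
            assert abs(np.mean(alphas) - h) < 0.1

    def test_invalid_h(self):
        with pytest.raises(ValueError):
            syn.fgn(100, 1.2, np.random.default_rng(0))


class TestGenerateTruth:
    def test_deterministic_given_seed(self):
        p = syn.GaitParams(duration=30, seed=5)
        a = syn.generate_truth(p)
        b = syn.generate_truth(p)
        assert np.array_equal(a.angles.angles, b.angles.angles)
        assert np.array_equal(a.contact_times["r"], b.contact_times["r"])
        c = syn.generate_truth(syn.GaitParams(duration=30, seed=6))
        assert not np.array_equal(a.angles.angles, c.angles.angles)

    def test_zero_variability_is_periodic(self):
        p = syn.GaitParams(duration=60, seed=1, stride_time_sd=0.0,
                           amp_sd_frac=0.0)
        truth = syn.generate_truth(p)
        fs = p.master_rate
        idx = np.round(truth.contact_times["r"] * fs).astype(int)
        ev = StrideSet(idx, idx / fs, fs)
        m = extract_strides(truth.angles, ev, discard_s=0.0, n_strides=30)
        assert mean_sd(m).max() < 0.05

    def test_stride_time_statistics(self):
        p = syn.GaitParams(duration=300, seed=3)
        truth = syn.generate_truth(p)
        d = truth.stride_durations
        assert abs(d.mean() - p.stride_time_mean) < 0.02
        assert abs(d.std() - p.stride_time_sd) < 0.01

    def test_amplitude_persistence_rank_orders_dfa(self):
        """Higher injected fluctuation persistence -> higher DFA of the
        per-stride ROM series (generator self-consistency)."""
        means = []
        for h in (0.5, 0.9):
            alphas = []
            for s in range(8):
                p = syn.GaitParams(duration=250, seed=100 + s, amp_h=h,
                                   still_duration=5)
                truth = syn.generate_truth(p)
                fs = p.master_rate
                idx = np.round(truth.contact_times["r"] * fs).astype(int)
                ev = StrideSet(idx, idx / fs, fs)
                m = extract_strides(truth.angles, ev, discard_s=5.0,
                                    n_strides=180)
                rom = m.data.max(axis=1) - m.data.min(axis=1)
                alphas.append(dfa_alpha(
                    rom[:, truth.angles.labels.index("hip_r_FE")]))
            means.append(np.mean(alphas))
        assert means[0] < means[1]

    def test_speed_condition_scales_rom_and_cadence(self):
        roms, tmeans = [], []
        for cond in ("speed_70", "speed_preferred", "speed_130"):
            p = syn.GaitParams(duration=40, seed=2).condition(cond)
            truth = syn.generate_truth(p)
            hip = truth.angles.column("hip_r_FE")[truth.t > 25]
            roms.append(hip.max() - hip.min())
            tmeans.append(truth.stride_durations.mean())
        assert roms[0] < roms[1] < roms[2]
        assert tmeans[0] > tmeans[1] > tmeans[2]

    def test_swing_condition_scales_trunk_axial(self):
        amps = {}
        for cond in ("swing_bound", "speed_preferred", "swing_active"):
            p = syn.GaitParams(duration=40, seed=2).condition(cond)
            truth = syn.generate_truth(p)
            tr = truth.angles.column("trunk_IE")[truth.t > 25]
            amps[cond] = tr.max() - tr.min()
        assert amps["swing_bound"] < amps["speed_preferred"] < amps["swing_active"]

    def test_still_period_is_neutral(self):
        truth = syn.generate_truth(syn.GaitParams(duration=30, seed=0))
        still = truth.t < truth.params.still_duration
        assert np.abs(truth.angles.angles[still]).max() < 1e-12


class TestSimulateImu:
    def test_static_pose_reads_gravity(self):
        p = syn.GaitParams(duration=15, still_duration=10, seed=1,
                           stride_time_sd=0.0, amp_sd_frac=0.0)
        truth = syn.generate_truth(p)
        noise = syn.SensorNoiseModel(gyro_noise_density=0.0,
                                     gyro_bias_walk=0.0, accel_noise_sd=0.0,
                                     marker_noise_mm=0.0)
        recs = syn.simulate_imu(truth, noise, seed=0)
        for rec in recs.values():
            still = rec.t < 8.0
            assert np.abs(rec.gyro[still]).max() < 1e-9
            norms = np.linalg.norm(rec.accel[still], axis=1)
            assert np.abs(norms - 9.80665).max() < 1e-6

    def test_zero_noise_fusion_roundtrip(self):
        p = syn.GaitParams(duration=20, still_duration=5, seed=2)
        truth = syn.generate_truth(p)
        noise = syn.SensorNoiseModel(gyro_noise_density=0.0,
                                     gyro_bias_walk=0.0, accel_noise_sd=0.0,
                                     mount_deg=0.0)
        recs = syn.simulate_imu(truth, noise, seed=0)
        rec = recs["pelvis"]
        track = fuse_trial(rec, beta=0.0)
        # fused track differs from the vendor-frame truth by a constant
        # heading; relative rotations over time must match exactly
        q_true = truth.orientations["pelvis"][::2]
        rel_est = rot.qmul(rot.qconj(track.q[0]), track.q)
        rel_true = rot.qmul(rot.qconj(q_true[0]), q_true)
        err = rot.geodesic_angle(
            rot.qmul(rel_est, rot.qconj(rel_est[0])),
            rot.qmul(rel_true, rot.qconj(rel_true[0])))
        # conjugated by the constant mount; compare geodesic magnitudes
        assert np.abs(np.degrees(
            rot.geodesic_angle(rel_est, rel_est[0])
            - rot.geodesic_angle(rel_true, rel_true[0]))).max() < 0.1

    def test_bias_walk_produces_detectable_drift(self):
        p = syn.GaitParams(duration=15, still_duration=400, seed=3,
                           stride_time_sd=0.0)
        truth = syn.generate_truth(p)
        noise = syn.SensorNoiseModel(gyro_noise_density=0.0,
                                     gyro_bias_walk=3e-4, accel_noise_sd=0.0,
                                     mount_deg=0.0)
        recs = syn.simulate_imu(truth, noise, seed=1)
        rec = recs["pelvis"]
        track = fuse_trial(rec, beta=0.0)
        ang, _ = rot.euler_zyx(track.q)
        still = rec.t < 390
        slope = np.polyfit(rec.t[still], np.unwrap(ang[still, 0]), 1)[0]
        # integrated bias walk shows up as heading drift
        assert abs(slope) > 1e-4

    def test_same_seed_identical(self):
        truth = syn.generate_truth(syn.GaitParams(duration=15, seed=4))
        a = syn.simulate_imu(truth, seed=9)
        b = syn.simulate_imu(truth, seed=9)
        for s in a:
            assert np.array_equal(a[s].gyro, b[s].gyro)
            assert np.array_equal(a[s].accel, b[s].accel)


class TestSimulateMarkers:
    def test_zero_noise_procrustes_recovers_truth(self):
        p = syn.GaitParams(duration=15, seed=5)
        truth = syn.generate_truth(p)
        noise = syn.SensorNoiseModel(marker_noise_mm=0.0)
        traj = syn.simulate_markers(truth, noise, seed=0)
        tracks = segment_orientation_from_markers(traj)
        for seg in ("pelvis", "femur_r", "foot_l"):
            err = rot.geodesic_angle(tracks[seg].q, truth.orientations[seg])
            assert err.max() < 1e-9

    def test_noise_bound(self):
        p = syn.GaitParams(duration=15, seed=5)
        truth = syn.generate_truth(p)
        traj = syn.simulate_markers(
            truth, syn.SensorNoiseModel(marker_noise_mm=1.0), seed=1)
        tracks = segment_orientation_from_markers(traj)
        err = np.degrees(rot.geodesic_angle(
            tracks["tibia_r"].q, truth.orientations["tibia_r"][::1]))
        assert np.percentile(err, 95) < 2.0

    def test_same_seed_identical(self):
        truth = syn.generate_truth(syn.GaitParams(duration=12, seed=6))
        a = syn.simulate_markers(truth, seed=3)
        b = syn.simulate_markers(truth, seed=3)
        for m in a.positions:
            assert np.array_equal(a.positions[m], b.positions[m])

    def test_rate_must_divide_master(self):
        truth = syn.generate_truth(syn.GaitParams(duration=12, seed=6))
        with pytest.raises(ValueError):
            syn.simulate_markers(truth, syn.SensorNoiseModel(marker_rate=100.0))
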