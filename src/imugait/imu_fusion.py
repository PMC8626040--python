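"""Magnetometer-free orientation estimation and drift removal.

The sensor-fusion stage turns each raw IMU stream (tri-axial accelerometer
in m/s^2 + gyroscope in rad/s, nominally 60 Hz) into a per-sample unit
quaternion track using Madgwick's gradient-descent complementary filter
without a magnetometer.  Residual slow orientation drift — the signature
of gyroscope bias that the accelerometer cannot observe about the vertical
— is then removed by fitting a line to each unwrapped ZYX Euler component
over the steady part of the trial and subtracting it when its slope
exceeds +/- 0.0010 rad/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import rotations as rot

__all__ = [
    "ImuRecording",
    "OrientationTrack",
    "DriftReport",
    "AxisDrift",
    "madgwick_step",
    "fuse_trial",
    "detrend_orientation",
    "read_imu_csv",
    "DRIFT_SLOPE_THRESHOLD",
]

#: |slope| above which a linear Euler-angle trend is treated as drift (rad/s)
DRIFT_SLOPE_THRESHOLD = 0.0010

#: default filter gain (rad/s); trades gyro trust against gravity correction
DEFAULT_BETA = 0.1

#: accelerometer norms below this fraction of g are treated as free-fall
_FREEFALL_FRAC = 0.1
#: gravity correction is gated to samples whose accelerometer norm lies
#: within this fraction of g — during dynamic phases the accelerometer
#: measures mostly linear acceleration and would pull the tilt away
_ACCEL_GATE_FRAC = 0.05
_G = 9.80665


@dataclass
class ImuRecording:
    """Raw inertial stream of one sensor.

    t is uniformly sampled (jitter < 1e-6 s); accel in m/s^2, gyro in rad/s.
    """

    sensor_id: str
    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.t.ndim != 1 or len(self.t) < 2:
            raise ValueError("recording needs at least 2 samples")
        if self.accel.shape != (len(self.t), 3) or self.gyro.shape != (len(self.t), 3):
            raise ValueError("accel/gyro must be (n, 3) matching t")
        if not (np.all(np.isfinite(self.accel)) and np.all(np.isfinite(self.gyro))):
            raise ValueError("non-finite samples in recording")
        dt = np.diff(self.t)
        if np.any(np.abs(dt - dt[0]) > 1e-6):
            raise ValueError("non-uniform sampling (jitter > 1e-6 s)")

    @property
    def fs(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])


@dataclass
class OrientationTrack:
    """Per-sample unit-quaternion orientation (sensor/segment -> world)."""

    sensor_id: str
    t: np.ndarray
    q: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (len(self.t), 4):
            raise ValueError("q must be (n, 4) matching t")


@dataclass
class AxisDrift:
    slope: float
    intercept: float
    detrended: bool


@dataclass
class DriftReport:
    """Per-Euler-axis linear fit over the detrending window."""

    yaw: AxisDrift
    pitch: AxisDrift
    roll: AxisDrift
    t_start: float = 20.0
    threshold: float = DRIFT_SLOPE_THRESHOLD

    def axes(self):
        return {"yaw": self.yaw, "pitch": self.pitch, "roll": self.roll}


@njit(cache=False)
def _madgwick_step_jit(q, gx, gy, gz, ax, ay, az, beta, dt):  # pragma: no cover
    w, x, y, z = q[0], q[1], q[2], q[3]
    # exact exponential-map strap-down integration of the gyro term
    # (first-order q + q_dot*dt accumulates degree-level error at gait
    # angular rates); with beta = 0 this reproduces pure integration
    ang = np.sqrt(gx * gx + gy * gy + gz * gz) * dt
    half = 0.5 * ang
    ew = np.cos(half)
    if ang > 1e-12:
        k = np.sin(half) / (ang / dt)  # = sin(half)/|omega|
    else:
        k = 0.5 * dt
    ex, ey, ez = k * gx, k * gy, k * gz
    nw = w * ew - x * ex - y * ey - z * ez
    nx = w * ex + x * ew + y * ez - z * ey
    ny = w * ey - x * ez + y * ew + z * ex
    nz = w * ez + x * ey - y * ex + z * ew
    anorm = np.sqrt(ax * ax + ay * ay + az * az)
    if beta > 0.0 and np.abs(anorm - _G) < _ACCEL_GATE_FRAC * _G:
        axn, ayn, azn = ax / anorm, ay / anorm, az / anorm
        # objective: predicted gravity (sensor frame) minus measured direction
        f1 = 2.0 * (x * z - w * y) - axn
        f2 = 2.0 * (w * x + y * z) - ayn
        f3 = 2.0 * (0.5 - x * x - y * y) - azn
        # gradient (J^T f); applied un-normalized so the correction vanishes
        # at equilibrium (the unit-normalized variant limit-cycles at
        # amplitude ~beta*dt instead of converging)
        sw = -2.0 * y * f1 + 2.0 * x * f2
        sx = 2.0 * z * f1 + 2.0 * w * f2 - 4.0 * x * f3
        sy = -2.0 * w * f1 + 2.0 * z * f2 - 4.0 * y * f3
        sz = 2.0 * x * f1 + 2.0 * y * f2
        nw -= beta * sw * dt
        nx -= beta * sx * dt
        ny -= beta * sy * dt
        nz -= beta * sz * dt
    n = np.sqrt(nw * nw + nx * nx + ny * ny + nz * nz)
    out = np.empty(4)
    out[0], out[1], out[2], out[3] = nw / n, nx / n, ny / n, nz / n
    return out


@njit(cache=False)
def _fuse_loop_jit(q0, gyro, accel, beta, dt):  # pragma: no cover
    n = gyro.shape[0]
    q = np.empty((n, 4))
    q[0] = q0
    cur = q0.copy()
    for i in range(1, n):
        cur = _madgwick_step_jit(
            cur,
            gyro[i, 0], gyro[i, 1], gyro[i, 2],
            accel[i, 0], accel[i, 1], accel[i, 2],
            beta, dt,
        )
        q[i] = cur
    return q


def madgwick_step(q, gyro, accel, beta: float, dt: float) -> np.ndarray:
    """One update of the gradient-descent-corrected quaternion rate equation.

    With ``beta = 0`` this is pure gyro strap-down integration; with zero
    angular rate and a persistent accelerometer reading, the estimate
    converges so that the sensor z-axis aligns with measured gravity.
    Accelerometer norms below 10% of g (free-fall) skip the corrective
    term and integrate the gyro only.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    q = rot.qnormalize(np.asarray(q, dtype=float))
    g = np.asarray(gyro, dtype=float)
    a = np.asarray(accel, dtype=float)
    if not (np.all(np.isfinite(g)) and np.all(np.isfinite(a))):
        raise ValueError("non-finite gyro/accel input")
    out = _madgwick_step_jit(q, g[0], g[1], g[2], a[0], a[1], a[2], beta, dt)
    return rot.qcanonical(out)


def _tilt_from_accel(accel_mean: np.ndarray) -> np.ndarray:
    """Initial orientation whose z-axis matches measured gravity, yaw = 0.

    The minimal rotation taking the measured specific-force direction to
    the world +z axis has no twist about the vertical, i.e. zero yaw.
    """
    a = np.asarray(accel_mean, dtype=float)
    n = np.linalg.norm(a)
    if n == 0:
        return rot.qidentity()
    a = a / n
    ez = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(a, ez))
    if c > 1.0 - 1e-12:
        return rot.qidentity()
    if c < -1.0 + 1e-12:
        return rot.from_axis_angle(np.array([1.0, 0.0, 0.0]), np.pi)
    axis = np.cross(a, ez)
    return rot.from_axis_angle(axis, float(np.arccos(np.clip(c, -1, 1))))


def fuse_trial(
    rec: ImuRecording,
    beta: float = DEFAULT_BETA,
    warmup: float = 1.0,
) -> OrientationTrack:
    """Fuse a full recording into an orientation track.

    The initial orientation is the tilt implied by the mean accelerometer
    reading over the first ``warmup`` seconds (assumed still), with zero
    yaw — heading is unobservable without a magnetometer and is fixed
    later by sensor-to-segment registration.
    """
    if rec.t[-1] - rec.t[0] < warmup:
        raise ValueError(
            f"recording ({rec.t[-1] - rec.t[0]:.2f} s) shorter than warmup {warmup} s"
        )
    dt = float(rec.t[1] - rec.t[0])
    n_init = max(1, int(round(warmup / dt)))
    q0 = _tilt_from_accel(rec.accel[:n_init].mean(axis=0))
    q = _fuse_loop_jit(q0, rec.gyro, rec.accel, float(beta), dt)
    return OrientationTrack(rec.sensor_id, rec.t.copy(), rot.qcanonical(q))


def detrend_orientation(
    track: OrientationTrack,
    t_start: float = 20.0,
    threshold: float = DRIFT_SLOPE_THRESHOLD,
) -> tuple[OrientationTrack, DriftReport]:
    """Identify and remove linear Euler-angle drift from an orientation track.

    Each unwrapped ZYX Euler component over ``[t_start, end]`` is fit by a
    least-squares line; components whose |slope| exceeds ``threshold``
    (rad/s) have the fitted trend, anchored so the correction is zero at
    ``t_start``, subtracted before converting back to quaternions.
    Sub-threshold components are left untouched.  Idempotent: a second
    pass finds only sub-threshold slopes.

    Gimbal-locked samples inside the window raise :class:`GimbalLockError`
    with the offending sample index.
    """
    t = track.t
    if t[-1] <= t_start:
        raise ValueError("track does not span beyond t_start")
    angles, lock = rot.euler_zyx(track.q)
    win = t >= t_start
    if np.any(lock & win):
        raise rot.GimbalLockError(np.flatnonzero(lock & win))
    angles = np.unwrap(angles, axis=0)
    out = angles.copy()
    names = ("yaw", "pitch", "roll")
    axes = {}
    tw = t[win]
    for i, name in enumerate(names):
        slope, intercept = np.polyfit(tw, angles[win, i], 1)
        detrended = abs(slope) > threshold
        if detrended:
            out[win, i] = angles[win, i] - slope * (tw - t_start)
        axes[name] = AxisDrift(float(slope), float(intercept), bool(detrended))
    q = rot.from_euler_zyx(out)
    new_track = OrientationTrack(track.sensor_id, t.copy(), q)
    report = DriftReport(axes["yaw"], axes["pitch"], axes["roll"], t_start, threshold)
    return new_track, report


def read_imu_csv(path, sensor_id: str | None = None) -> dict[str, ImuRecording]:
    """Read IMU recordings from CSV.

    Expected columns: ``t, ax, ay, az, gx, gy, gz`` and optionally
    ``sensor_id`` (long format, several sensors per file).  Units: seconds,
    m/s^2, rad/s.  Returns a dict keyed by sensor id.
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"IMU CSV missing columns: {missing}")
    out = {}
    if "sensor_id" in df.columns:
        groups = df.groupby("sensor_id", sort=False)
    else:
        groups = [(sensor_id or "imu", df)]
    for sid, g in groups:
        out[str(sid)] = ImuRecording(
            str(sid),
            g["t"].to_numpy(),
            g[["ax", "ay", "az"]].to_numpy(),
            g[["gx", "gy", "gz"]].to_numpy(),
        )
    return out


def write_imu_csv(path, recordings: dict[str, ImuRecording]) -> None:
    """Write one or more recordings in the long CSV format of read_imu_csv."""
    import pandas as pd

    frames = []
    for sid, rec in recordings.items():
        frames.append(
            pd.DataFrame(
                {
                    "sensor_id": sid,
                    "t": rec.t,
                    "ax": rec.accel[:, 0],
                    "ay": rec.accel[:, 1],
                    "az": rec.accel[:, 2],
                    "gx": rec.gyro[:, 0],
                    "gy": rec.gyro[:, 1],
                    "gz": rec.gyro[:, 2],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
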