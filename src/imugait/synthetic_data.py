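"""Synthetic treadmill-gait generator with known ground truth.

Produces 7-minute constant-speed trials at three speeds and three
arm-swing conditions: a still neutral-standing period (used for sensor
registration and drift-fit anchoring) followed by continuous strides.
Stride-to-stride structure is injected at the stride level — durations
and per-DOF amplitude multipliers are fractional-Gaussian-noise series
with configurable SD and Hurst persistence — so that the divergence,
persistence and regularity metrics see realistic temporal structure,
while pointwise sensor noise is left to the measurement layer:

* :func:`simulate_imu` renders each segment's orientation into a raw
  60 Hz IMU stream (gyro from quaternion differentiation plus bias
  random walk and white noise; accelerometer as rotated gravity plus
  segment linear acceleration plus white noise) in a sensor frame with a
  random mounting offset and the vendor axis convention.
* :func:`simulate_markers` renders rigid four-marker clusters at 120 Hz
  with isotropic Gaussian noise.

Arm-swing conditions act on trunk/pelvis axial amplitudes (the chain has
no arms); speed conditions scale lower-limb amplitudes and stride time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import rotations as rot
from .imu_fusion import ImuRecording
from .kinematics import (
    ChainModel,
    JointAngleSeries,
    MarkerTrajectories,
    forward_kinematics,
)
from .kinematics import _FRAME_SEQ  # vendor-to-model axis convention

__all__ = [
    "GaitParams",
    "SensorNoiseModel",
    "TruthData",
    "fgn",
    "generate_truth",
    "simulate_imu",
    "simulate_markers",
    "CONDITIONS",
]

_G_VEC = np.array([0.0, 0.0, -9.80665])

#: the five study conditions: (speed factor, swing condition)
CONDITIONS = {
    "speed_preferred": (1.0, "preferred"),
    "speed_70": (0.7, "preferred"),
    "speed_130": (1.3, "preferred"),
    "swing_active": (1.0, "active"),
    "swing_bound": (1.0, "bound"),
}

# trunk/pelvis and non-sagittal patterns over the gait cycle, degrees:
# label -> (offset, [(harmonic k, amplitude, phase rad), ...]);
# angle(phi) = offset + sum A cos(2 pi k phi - phase).  Right-side cycle
# starts at right heel strike; the left side is shifted by half a cycle.
# The sagittal leg patterns (hip/knee/ankle FE) are derived from the
# treadmill foot-path construction in _leg_cycle instead.
_BASE_PATTERN = {
    "pelvis_FE": (6.0, [(2, 1.5, 0.5)]),
    "pelvis_AA": (0.0, [(1, 2.5, 1.0)]),
    "pelvis_IE": (0.0, [(1, 5.0, 2.8)]),
    "trunk_FE": (-4.0, [(2, 1.5, 3.0)]),
    "trunk_AA": (0.0, [(1, 3.0, 4.2)]),
    "trunk_IE": (0.0, [(1, 6.0, -0.4)]),
    "hip_AA": (0.0, [(1, 2.0, 5.5)]),
    "hip_IE": (0.0, [(1, 3.0, 3.5)]),
    "ankle_AA": (0.0, [(1, 3.0, 2.2)]),
}

#: fraction of the cycle spent in stance
_STANCE_FRAC = 0.62

#: DOF groups scaled by the arm-swing condition (trunk and pelvis axial
#: rotation; the chain has no arm segments)
_SWING_SCALED = ("trunk_AA", "trunk_IE", "pelvis_IE")
_SWING_MULT = {"preferred": 1.0, "active": 1.4, "bound": 0.65}


def _fit_harmonics(y: np.ndarray, kmax: int = 10):
    """Fourier-fit a periodic cycle: returns (offset, [(k, A, phase)])."""
    n = len(y)
    c = np.fft.rfft(y) / n
    harm = []
    for k in range(1, min(kmax, len(c) - 1) + 1):
        a = 2 * np.abs(c[k])
        if a > 1e-9:
            harm.append((k, float(a), float(-np.angle(c[k]))))
    return float(c[0].real), harm


def _leg_cycle(params: "GaitParams", n: int = 512):
    """Sagittal hip/knee/ankle flexion cycles from a treadmill foot path.

    The ankle joint centre sweeps backward under the hip at belt speed
    during stance and returns along a smooth lifted arc during swing; the
    2-link (femur, tibia) closed-form IK turns that path into hip and
    knee angles, and the ankle keeps the grounded foot flat.  This guarantees a
    foot-speed profile with a single dominant swing maximum followed by
    a contact minimum — the signature heel-strike detection relies on.
    """
    l1, l2 = 0.41, 0.43
    reach = l1 + l2
    tmean = params.stride_time_mean / np.sqrt(params.speed_factor)
    v = params.speed * params.speed_factor
    half_sweep = v * _STANCE_FRAC * tmean / 2.0
    sin_g = min(half_sweep / reach, 0.55)
    gamma_a = np.arcsin(sin_g)  # leg angle from vertical at contact
    k_swing = 0.13 * np.sqrt(params.speed_factor)  # swing leg shortening
    phi = np.arange(n) / n
    gamma = np.empty(n)
    st = phi < _STANCE_FRAC
    u = phi[st] / _STANCE_FRAC
    gamma[st] = gamma_a * (1 - 2 * u)
    # heel lift starts in late stance (heel-off) and returns to the
    # ground with zero velocity at contact; starting the lift before the
    # swing reversal keeps the heel speed rising monotonically through
    # toe-off (no spurious speed minimum there)
    heel_off = 0.45
    lift = np.zeros(n)
    lifting = phi >= heel_off
    lift[lifting] = np.sin(
        np.pi * (phi[lifting] - heel_off) / (1 - heel_off)
    ) ** 2
    ell = reach * (1 - 0.010 * np.sin(np.pi * np.clip(phi / _STANCE_FRAC, 0, 1)) ** 2
                   - k_swing * lift)
    u = (phi[~st] - _STANCE_FRAC) / (1 - _STANCE_FRAC)
    # quintic swing return whose end slopes match the stance sweep rate,
    # so the foot speed is C1-continuous at contact and toe-off (velocity
    # jumps would ring through the harmonic fit and fake extra speed
    # peaks)
    d = -(1 - _STANCE_FRAC) / _STANCE_FRAC
    A = np.array([
        [0, 0, 0, 0, 0, 1],        # p(0) = 0
        [1, 1, 1, 1, 1, 1],        # p(1) = 1
        [0, 0, 0, 0, 1, 0],        # p'(0) = d
        [5, 4, 3, 2, 1, 0],        # p'(1) = d
        [0, 0, 0, 2, 0, 0],        # p''(0) = 0
        [20, 12, 6, 2, 0, 0],      # p''(1) = 0
    ])
    coef = np.linalg.solve(A, np.array([0.0, 1.0, d, d, 0.0, 0.0]))
    s = np.polyval(coef, u)
    gamma[~st] = gamma_a * (2 * s - 1)
    # closed-form planar 2-link IK (FE rotations about +Y: positive tilts
    # the limb backward, so forward lean is negative hip FE)
    c2 = (ell**2 - l1**2 - l2**2) / (2 * l1 * l2)
    knee = np.arccos(np.clip(c2, -1.0, 1.0))
    hip = -gamma - np.arctan2(l2 * np.sin(knee), l1 + l2 * np.cos(knee))
    # ankle keeps the foot flat while it is on the ground but lets it
    # pitch partially with the shank in swing (a rigidly level foot
    # would need an unrealistic ~80 deg ankle excursion)
    ankle = -(hip + knee) * (1.0 - 0.55 * lift)
    return (np.degrees(hip), np.degrees(knee), np.degrees(ankle))


@dataclass
class GaitParams:
    """Ground-truth gait generation settings (one trial).

    Stride durations are mean + SD x fGn(H); per-DOF amplitude
    multipliers are 1 + SD-fraction x fGn(H).  The speed factor scales
    lower-limb amplitudes proportionally and shortens the stride time by
    its square root; arm-swing conditions scale trunk/pelvis axial
    amplitudes.
    """

    speed: float = 1.1  # preferred belt speed, m/s
    stride_time_mean: float = 1.10  # s at preferred speed
    stride_time_sd: float = 0.022  # s (~2% CV, healthy treadmill gait)
    stride_time_h: float = 0.75  # Hurst persistence of stride times
    amp_sd_frac: float = 0.025  # per-stride amplitude variability
    amp_h: float = 0.75
    speed_factor: float = 1.0  # 0.7 / 1.0 / 1.3
    swing: str = "preferred"  # preferred / active / bound
    duration: float = 420.0  # walking time, s ("seven minutes")
    still_duration: float = 20.0  # neutral standing before walking, s
    master_rate: float = 120.0  # Hz of the ground-truth sampling
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.stride_time_h < 1 and 0 < self.amp_h < 1):
            raise ValueError("Hurst exponents must lie in (0, 1)")
        if self.stride_time_sd < 0 or self.amp_sd_frac < 0:
            raise ValueError("variability SDs must be non-negative")
        if self.duration <= 0 or self.still_duration < 0:
            raise ValueError("durations must be positive")
        if self.swing not in _SWING_MULT:
            raise ValueError(f"unknown swing condition {self.swing!r}")

    def condition(self, name: str) -> "GaitParams":
        """This parameter set under one of the named study conditions."""
        sf, sw = CONDITIONS[name]
        return replace(self, speed_factor=sf, swing=sw)


@dataclass
class SensorNoiseModel:
    """Measurement-layer noise at the two sampling rates."""

    gyro_noise_density: float = 0.005  # rad/s/sqrt(Hz) white noise
    gyro_bias_walk: float = 1e-4  # rad*s^-3/2 bias random walk
    accel_noise_sd: float = 0.05  # m/s^2 per-sample white noise
    marker_noise_mm: float = 0.5  # isotropic marker jitter
    imu_rate: float = 60.0
    marker_rate: float = 120.0
    mount_deg: float = 12.0  # max random sensor-mounting misalignment

    def __post_init__(self):
        for f in ("gyro_noise_density", "gyro_bias_walk", "accel_noise_sd",
                  "marker_noise_mm", "mount_deg"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")


@dataclass
class TruthData:
    """Ground truth of one simulated trial."""

    params: GaitParams
    model: ChainModel
    t: np.ndarray  # master clock, s
    angles: JointAngleSeries  # ground-truth joint angles (deg)
    orientations: dict  # segment -> (n, 4) world quaternions
    positions: dict  # segment origin / tracking point -> (n, 3) m
    contact_times: dict  # foot ("r"/"l") -> ground-truth heel strikes, s
    stride_starts: np.ndarray  # right-cycle stride start times, s
    stride_durations: np.ndarray


def fgn(n: int, h: float, rng: np.random.Generator) -> np.ndarray:
    """Fractional Gaussian noise of unit variance via circulant embedding
    (Davies-Harte).  ``h = 0.5`` reduces to iid Gaussian noise."""
    if not 0 < h < 1:
        raise ValueError("Hurst exponent must lie in (0, 1)")
    if n < 2:
        return rng.standard_normal(n)
    if abs(h - 0.5) < 1e-12:
        return rng.standard_normal(n)
    k = np.arange(n)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * h) - 2 * np.abs(k) ** (2 * h)
        + np.abs(k - 1) ** (2 * h)
    )
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    m = len(row)
    lam = np.fft.fft(row).real
    lam = np.maximum(lam, 0.0)  # clip tiny negative eigenvalues
    # complex Gaussian spectrum with Hermitian symmetry
    v = np.empty(m, dtype=complex)
    half = m // 2
    v[0] = rng.standard_normal() * np.sqrt(m)
    v[half] = rng.standard_normal() * np.sqrt(m)
    re = rng.standard_normal(half - 1)
    im = rng.standard_normal(half - 1)
    v[1:half] = (re + 1j * im) * np.sqrt(m / 2.0)
    v[half + 1:] = np.conj(v[1:half][::-1])
    x = np.fft.ifft(np.sqrt(lam) * v).real[:n]
    return x


def _shift_harm(harm, shift):
    """Advance a harmonic set by a cycle-phase shift (baked into phases)."""
    return [(k, a, ph + 2 * np.pi * k * shift) for k, a, ph in harm]


def _neg_harm(harm):
    return [(k, a, ph + np.pi) for k, a, ph in harm]


def _pattern_tables(model: ChainModel, params: GaitParams):
    """Per-DOF (offset, harmonics) under the trial condition.

    Sagittal leg DOFs come from the foot-path construction (which embeds
    the speed condition); trunk/pelvis and non-sagittal DOFs come from
    the fixed harmonic table, with the arm-swing condition scaling the
    axial-rotation amplitudes.  Left-side DOFs are shifted half a cycle
    (encoded in the harmonic phases).  Hip DOFs additionally carry the
    negated pelvis harmonics: the stance leg counter-rotates so pelvis
    wobble does not propagate into the foot path — on a treadmill the
    grounded foot moves with the belt, not with the pelvis.
    """
    hip, knee, ankle = _leg_cycle(params)
    leg_fits = {
        "hip_FE": _fit_harmonics(hip),
        "knee_FE": _fit_harmonics(knee),
        "ankle_FE": _fit_harmonics(ankle),
    }
    swing_mult = _SWING_MULT[params.swing]

    def base(key):
        off, harm = _BASE_PATTERN[key]
        if key in _SWING_SCALED:
            harm = [(kk, aa * swing_mult, ph) for kk, aa, ph in harm]
        return off, harm

    tables = {}
    for d in model.dof_labels:
        parts = d.split("_")
        side_shift = 0.5 if parts[1] == "l" and parts[0] in (
            "hip", "knee", "ankle") else 0.0
        base_key = d.replace("_l_", "_").replace("_r_", "_")
        if base_key in leg_fits:
            off, harm = leg_fits[base_key]
        else:
            off, harm = base(base_key)
        harm = _shift_harm(harm, side_shift)
        if parts[0] == "hip":
            _, pharm = base("pelvis_" + parts[-1])
            harm = harm + _neg_harm(pharm)
        tables[d] = (off, harm)
    return tables


def _eval_pattern(off, harm, phi):
    out = np.full_like(phi, off, dtype=float)
    for k, a, ph in harm:
        out += a * np.cos(2 * np.pi * k * phi - ph)
    return out


def _contact_phase(model: ChainModel, params: GaitParams, foot: str) -> float:
    """Cycle phase of heel strike: the foot-speed minimum that follows the
    mid-swing speed maximum of the noiseless nominal cycle."""
    tables = _pattern_tables(model, params)
    tmean = params.stride_time_mean / np.sqrt(params.speed_factor)
    nph = 400
    phi = np.arange(2 * nph) / nph  # two cycles to wrap the search
    angles = np.column_stack(
        [_eval_pattern(off, harm, phi) for off, harm in tables.values()]
    )
    _, pos = forward_kinematics(model, angles)
    p = pos[f"calcn_{foot}"]
    v = np.gradient(p, tmean / nph, axis=0)
    speed = np.linalg.norm(v, axis=1)
    one = speed[nph // 2: nph + nph // 2]  # one full cycle, arbitrary origin
    imax = int(np.argmax(one))
    rel = np.roll(one, -imax)
    imin = int(np.argmin(rel[: nph // 2]))  # first minimum after the max
    return ((nph // 2 + imax + imin) % nph) / nph


def generate_truth(
    params: GaitParams, model: ChainModel | None = None
) -> TruthData:
    """Generate ground-truth kinematics for one trial.

    Stride durations and per-DOF amplitude multipliers are drawn as
    fractional Gaussian noise; the base cycle pattern is warped to each
    stride's duration.  A cosine onset ramp over the first 1.5 s of
    walking blends the neutral standing pose into the gait pattern.
    Deterministic given ``params.seed``.
    """
    if params.duration < 10:
        raise ValueError("walking duration must be at least 10 s")
    model = model or ChainModel.default("2dof")
    rng = np.random.default_rng(params.seed)
    tables = _pattern_tables(model, params)
    tmean = params.stride_time_mean / np.sqrt(params.speed_factor)
    n_strides = int(np.ceil(params.duration / (0.6 * tmean))) + 2
    durs = tmean + params.stride_time_sd * fgn(
        n_strides, params.stride_time_h, rng
    )
    durs = np.clip(durs, 0.5 * tmean, 1.5 * tmean)
    amp = {
        d: 1.0 + params.amp_sd_frac * fgn(n_strides, params.amp_h, rng)
        for d in tables
    }
    starts = params.still_duration + np.concatenate([[0.0], np.cumsum(durs)])
    total = params.still_duration + params.duration
    fs = params.master_rate
    t = np.arange(int(round(total * fs))) / fs
    walking = t >= params.still_duration
    idx = np.clip(np.searchsorted(starts, t[walking], side="right") - 1,
                  0, n_strides - 1)
    phi_r = (t[walking] - starts[idx]) / durs[idx] + idx
    ramp = np.clip((t[walking] - params.still_duration) / 1.5, 0.0, 1.0)
    ramp = 0.5 - 0.5 * np.cos(np.pi * ramp)
    nd = model.n_dofs
    angles = np.zeros((len(t), nd))
    for j, d in enumerate(model.dof_labels):
        off, harm = tables[d]
        a = _eval_pattern(off, harm, phi_r - idx)
        # amplitude variability scales the deviation from the offset
        angles[walking, j] = ramp * (off + amp[d][idx] * (a - off))
    series = JointAngleSeries(t, angles, model.dof_labels)
    # pelvis bob: two vertical bounces and one lateral sway per stride
    pelvis_pos = np.tile(model.geometry["pelvis"], (len(t), 1)).astype(float)
    pelvis_pos[walking, 2] += 0.015 * ramp * np.cos(4 * np.pi * phi_r)
    pelvis_pos[walking, 1] += 0.020 * ramp * np.sin(2 * np.pi * phi_r)
    orient, pos = forward_kinematics(model, angles, pelvis_pos=pelvis_pos)
    contact = {}
    for foot in ("r", "l"):
        # the pattern tables already encode the half-cycle side shift, so
        # the per-foot contact phase comes straight out of the nominal FK
        phc = _contact_phase(model, params, foot)
        times = starts[:-1] + (phc % 1.0) * durs
        times = times[times <= t[-1]]
        # the onset ramp makes the first strides unrepresentative
        contact[foot] = times[times >= params.still_duration + 2 * tmean]
    return TruthData(params, model, t, series, orient, pos, contact,
                     starts[:-1], durs)


_SENSOR_OFFSETS = {
    "pelvis": np.array([-0.08, 0.0, 0.02]),
    "trunk": np.array([-0.06, 0.0, 0.25]),
    "femur_r": np.array([0.04, -0.03, -0.20]),
    "femur_l": np.array([0.04, 0.03, -0.20]),
    "tibia_r": np.array([0.03, -0.02, -0.20]),
    "tibia_l": np.array([0.03, 0.02, -0.20]),
    "foot_r": np.array([0.02, 0.0, -0.03]),
    "foot_l": np.array([0.02, 0.0, -0.03]),
}


def _angular_velocity(q: np.ndarray, dt: float) -> np.ndarray:
    """Body-frame angular velocity from successive quaternions."""
    qrel = rot.qmul(rot.qconj(q[:-1]), q[1:])
    w = rot.to_rotvec(qrel) / dt
    # sample i holds the mean rate over (i-1, i], matching how a
    # strap-down integrator consumes it
    return np.vstack([w[:1], w])


def simulate_imu(
    truth: TruthData,
    noise: SensorNoiseModel | None = None,
    seed: int = 0,
) -> dict[str, ImuRecording]:
    """Render ground-truth segment motion into raw IMU streams.

    Each segment carries one sensor at a fixed anatomical offset with a
    random mounting misalignment (up to ``mount_deg``) and the vendor
    axis convention (the inverse of the fixed sensor-to-model rotation
    sequence).  Gyro = exact body rates + bias random walk + white
    noise; accelerometer = specific force (gravity + linear acceleration
    of the sensor point) + white noise.  Sampled at ``imu_rate``.
    """
    noise = noise or SensorNoiseModel()
    rng = np.random.default_rng(seed)
    fs_m = truth.params.master_rate
    step = int(round(fs_m / noise.imu_rate))
    if abs(fs_m / noise.imu_rate - step) > 1e-9:
        raise ValueError("imu_rate must divide the master rate")
    dt = step / fs_m
    out = {}
    for seg in truth.orientations:
        if seg not in _SENSOR_OFFSETS:
            continue
        axis = rng.standard_normal(3)
        mount = rot.from_axis_angle(
            axis, np.radians(noise.mount_deg) * rng.uniform(0.2, 1.0)
        )
        q_seg = truth.orientations[seg]
        q_vendor = rot.qmul(rot.qmul(q_seg, mount), rot.qconj(_FRAME_SEQ))
        # sensor point in world coordinates at the master rate
        p = truth.positions[seg] + rot.qrotate(q_seg, _SENSOR_OFFSETS[seg])
        acc_w = np.gradient(np.gradient(p, 1 / fs_m, axis=0), 1 / fs_m, axis=0)
        qs = q_vendor[::step]
        n = len(qs)
        gyro = _angular_velocity(qs, dt)
        bias = np.cumsum(
            rng.normal(0.0, noise.gyro_bias_walk * np.sqrt(dt), (n, 3)), axis=0
        )
        gyro = gyro + bias + rng.normal(
            0.0, noise.gyro_noise_density * np.sqrt(noise.imu_rate / 2), (n, 3)
        )
        spec_force = rot.qrotate(rot.qconj(qs), acc_w[::step] - _G_VEC)
        accel = spec_force + rng.normal(0.0, noise.accel_noise_sd, (n, 3))
        out[seg] = ImuRecording(seg, np.arange(n) * dt, accel, gyro)
    return out


def _cluster_template() -> dict[str, np.ndarray]:
    # rigid four-marker cluster, ~100 mm span, non-coplanar
    return {
        "a": np.array([0.0, 0.0, 0.0]),
        "b": np.array([95.0, 0.0, 10.0]),
        "c": np.array([10.0, 90.0, 0.0]),
        "d": np.array([45.0, 40.0, 70.0]),
    }


def simulate_markers(
    truth: TruthData,
    noise: SensorNoiseModel | None = None,
    seed: int = 0,
) -> MarkerTrajectories:
    """Render rigid marker clusters (mm) at the optoelectronic rate."""
    noise = noise or SensorNoiseModel()
    rng = np.random.default_rng(seed)
    fs_m = truth.params.master_rate
    step = int(round(fs_m / noise.marker_rate))
    if abs(fs_m / noise.marker_rate - step) > 1e-9:
        raise ValueError("marker_rate must divide the master rate")
    positions = {}
    marker_segments = {}
    templates = {}
    t = truth.t[::step]
    for seg in truth.orientations:
        if seg not in _SENSOR_OFFSETS:
            continue
        tmpl = _cluster_template()
        templates[seg] = tmpl
        q = truth.orientations[seg][::step]
        origin_mm = (
            truth.positions[seg][::step]
            + rot.qrotate(q, _SENSOR_OFFSETS[seg])
        ) * 1000.0
        for mid, local in tmpl.items():
            name = f"{seg}:{mid}"
            marker_segments[name] = seg
            p = origin_mm + rot.qrotate(q, local)
            positions[name] = p + rng.normal(0.0, noise.marker_noise_mm,
                                             p.shape)
    # template keys must match the trajectory marker ids
    templates = {
        seg: {f"{seg}:{mid}": v for mid, v in tmpl.items()}
        for seg, tmpl in templates.items()
    }
    return MarkerTrajectories(t, positions, marker_segments, templates)
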