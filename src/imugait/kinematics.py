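"""Joint-chain model, registration, forward and inverse kinematics.

The biomechanical model is a rotation-only kinematic tree: pelvis floating
relative to ground (3 rotational DOF: tilt, obliquity, rotation), a 3-DOF
trunk on the pelvis, and per leg a 3-DOF hip, 1-DOF knee (flexion) and a
1- or 2-DOF ankle (flexion, optionally inversion).  All neutral-pose
segment frames coincide with the model frame: X anterior, Y left, Z up.
Within each joint the DOF order is FE -> AA -> IE (intrinsic rotations
about Y, X, Z respectively); joint angles are reported in degrees.

Two measurement paths produce segment-orientation targets for the same
orientation-tracking inverse kinematics:

* IMU path: fused sensor quaternions, converted to the model axis
  convention, then registered (mounting offset + heading) in a neutral
  standing pose.
* reference path: least-squares (orthogonal Procrustes) orientations of
  rigid four-marker clusters tracked optoelectronically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import rotations as rot
from .imu_fusion import OrientationTrack

__all__ = [
    "Joint",
    "ChainModel",
    "JointAngleSeries",
    "MarkerTrajectories",
    "RegistrationResult",
    "sensor_to_model_frame",
    "register",
    "forward_kinematics",
    "ik_orientation",
    "segment_orientation_from_markers",
    "pose_offset_alignment",
]

_AXES = {
    "X": np.array([1.0, 0.0, 0.0]),
    "Y": np.array([0.0, 1.0, 0.0]),
    "Z": np.array([0.0, 0.0, 1.0]),
}
# anatomical rotation components: flexion/extension about the mediolateral
# axis, abduction/adduction about the anterior axis, internal/external
# rotation about the longitudinal (vertical-in-neutral) axis
_DOF_AXIS = {"FE": "Y", "AA": "X", "IE": "Z"}


@dataclass(frozen=True)
class Joint:
    name: str
    parent: str  # parent segment ("ground" for the root joint)
    child: str
    dofs: tuple[str, ...]  # DOF labels, each "<joint>_<FE|AA|IE>"


@dataclass
class ChainModel:
    """Tree-structured rotation-only joint chain.

    ``geometry`` maps child segment -> offset (m) of its origin in the
    parent segment frame; ``points`` maps named tracking points (e.g. the
    calcaneus used for heel-strike detection) -> (segment, local offset).
    """

    joints: list[Joint]
    ankle_mode: str = "2dof"
    geometry: dict[str, np.ndarray] = field(default_factory=dict)
    points: dict[str, tuple[str, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self):
        if self.ankle_mode not in ("1dof", "2dof"):
            raise ValueError("ankle_mode must be '1dof' or '2dof'")
        seen = set()
        for j in self.joints:
            for d in j.dofs:
                if d in seen:
                    raise ValueError(f"DOF {d} assigned to more than one joint")
                seen.add(d)

    @property
    def dof_labels(self) -> list[str]:
        return [d for j in self.joints for d in j.dofs]

    @property
    def n_dofs(self) -> int:
        return len(self.dof_labels)

    @property
    def segments(self) -> list[str]:
        return [j.child for j in self.joints]

    @property
    def analysis_dofs(self) -> list[str]:
        """The per-joint angles reported as outcomes (right side + axial)."""
        return [
            d
            for d in self.dof_labels
            if not d.startswith(("hip_l", "knee_l", "ankle_l"))
        ]

    @classmethod
    def default(cls, ankle_mode: str = "2dof") -> "ChainModel":
        joints = [
            Joint("pelvis", "ground", "pelvis",
                  ("pelvis_FE", "pelvis_AA", "pelvis_IE")),
            Joint("trunk", "pelvis", "trunk",
                  ("trunk_FE", "trunk_AA", "trunk_IE")),
        ]
        for side in ("r", "l"):
            joints.append(Joint(f"hip_{side}", "pelvis", f"femur_{side}",
                                (f"hip_{side}_FE", f"hip_{side}_AA",
                                 f"hip_{side}_IE")))
            joints.append(Joint(f"knee_{side}", f"femur_{side}",
                                f"tibia_{side}", (f"knee_{side}_FE",)))
            ankle_dofs = (f"ankle_{side}_FE",)
            if ankle_mode == "2dof":
                ankle_dofs = (f"ankle_{side}_FE", f"ankle_{side}_AA")
            joints.append(Joint(f"ankle_{side}", f"tibia_{side}",
                                f"foot_{side}", ankle_dofs))
        geometry = {
            "pelvis": np.array([0.0, 0.0, 1.0]),
            "trunk": np.array([0.0, 0.0, 0.10]),
            "femur_r": np.array([0.0, -0.09, 0.0]),
            "femur_l": np.array([0.0, 0.09, 0.0]),
            "tibia_r": np.array([0.0, 0.0, -0.41]),
            "tibia_l": np.array([0.0, 0.0, -0.41]),
            "foot_r": np.array([0.0, 0.0, -0.43]),
            "foot_l": np.array([0.0, 0.0, -0.43]),
        }
        points = {
            "calcn_r": ("foot_r", np.array([-0.05, 0.0, -0.05])),
            "calcn_l": ("foot_l", np.array([-0.05, 0.0, -0.05])),
        }
        return cls(joints, ankle_mode, geometry, points)


@dataclass
class JointAngleSeries:
    """Per-DOF joint-angle time series in degrees."""

    t: np.ndarray
    angles: np.ndarray  # (n, n_dofs) deg
    labels: list[str]

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.shape != (len(self.t), len(self.labels)):
            raise ValueError("angles must be (len(t), len(labels))")
        if not np.all(np.isfinite(self.angles)):
            raise ValueError("non-finite joint angles")

    @property
    def fs(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])

    def column(self, label: str) -> np.ndarray:
        return self.angles[:, self.labels.index(label)]

    def resample(self, t_new: np.ndarray) -> "JointAngleSeries":
        t_new = np.asarray(t_new, dtype=float)
        out = np.column_stack(
            [np.interp(t_new, self.t, self.angles[:, i])
             for i in range(self.angles.shape[1])]
        )
        return JointAngleSeries(t_new, out, list(self.labels))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.angles, index=pd.Index(self.t, name="t"),
                            columns=self.labels)


@dataclass
class MarkerTrajectories:
    """Optoelectronic marker positions (mm) with rigid cluster templates.

    ``templates`` gives each tracked segment's marker layout in the
    segment frame at calibration; >= 3 non-collinear markers per segment.
    """

    t: np.ndarray
    positions: dict[str, np.ndarray]  # marker_id -> (n, 3) mm, world frame
    marker_segments: dict[str, str]  # marker_id -> segment_id
    templates: dict[str, dict[str, np.ndarray]]  # segment -> marker -> (3,) mm

    def segment_markers(self, segment: str) -> list[str]:
        return [m for m, s in self.marker_segments.items() if s == segment]


@dataclass
class RegistrationResult:
    """Fixed sensor-to-segment offsets established at the neutral pose."""

    offsets: dict[str, np.ndarray]  # sensor -> quaternion (sensor -> segment)
    headings: dict[str, float]  # sensor -> heading (yaw) removed, rad
    mean_heading: float = 0.0

    def apply(self, track: OrientationTrack) -> OrientationTrack:
        """Map a sensor orientation track to its segment orientation."""
        sid = track.sensor_id
        head = rot.from_axis_angle(_AXES["Z"], -self.headings[sid])
        q = rot.qmul(rot.qmul(head, track.q), rot.qconj(self.offsets[sid]))
        return OrientationTrack(sid, track.t.copy(), q)


# fixed axis-convention change between the raw sensor frame and the model
# frame: body-fixed rotations of 180 deg about x, 90 deg about y, -90 deg
# about z, applied in that order
_FRAME_SEQ = rot.qmul(
    rot.qmul(
        rot.from_axis_angle(_AXES["X"], np.pi),
        rot.from_axis_angle(_AXES["Y"], np.pi / 2),
    ),
    rot.from_axis_angle(_AXES["Z"], -np.pi / 2),
)


def sensor_to_model_frame(q: np.ndarray) -> np.ndarray:
    """Re-express orientations after the fixed body-fixed rotation sequence.

    Body-fixed (intrinsic) rotations compose by right-multiplication, so
    the identity maps to the composite rotation itself.
    """
    return rot.qmul(q, _FRAME_SEQ)


def _quat_mean(q: np.ndarray) -> np.ndarray:
    """Chordal mean of nearby unit quaternions (sign-aligned to the first)."""
    q = np.atleast_2d(q)
    sign = np.where(np.sum(q * q[0], axis=-1, keepdims=True) < 0, -1.0, 1.0)
    return rot.qcanonical(rot.qnormalize(np.mean(q * sign, axis=0)))


def register(
    neutral_tracks: dict[str, np.ndarray],
    model: ChainModel,
    gyro_windows: dict[str, np.ndarray] | None = None,
    gyro_rms_max: float = 0.05,
) -> RegistrationResult:
    """Sensor-to-segment registration from a neutral standing pose.

    ``neutral_tracks`` maps each sensor id (= segment id) to a single
    quaternion or a short still window of quaternions (averaged).  The
    heading (yaw) of each sensor is unobservable to magnetometer-free
    fusion, so each sensor's heading is measured, referenced to the
    circular-mean heading across sensors, and removed so the registered
    pose faces the model's anterior-posterior axis.  The residual rotation
    is the fixed mounting offset; at the neutral pose the registered
    segment orientations equal the model's neutral frames exactly.

    If ``gyro_windows`` are given, a calibration window whose gyro RMS
    exceeds ``gyro_rms_max`` (rad/s) raises — the pose was not still.
    """
    if gyro_windows is not None:
        for sid, g in gyro_windows.items():
            rms = float(np.sqrt(np.mean(np.asarray(g) ** 2)))
            if rms > gyro_rms_max:
                raise ValueError(
                    f"calibration window not still: sensor {sid} gyro RMS "
                    f"{rms:.3f} rad/s > {gyro_rms_max}"
                )
    means = {sid: _quat_mean(q) for sid, q in neutral_tracks.items()}
    yaws = {}
    for sid, q in means.items():
        ang, _ = rot.euler_zyx(q)
        yaws[sid] = float(np.atleast_2d(ang)[0, 0])
    mean_heading = float(
        np.arctan2(
            np.mean([np.sin(y) for y in yaws.values()]),
            np.mean([np.cos(y) for y in yaws.values()]),
        )
    )
    offsets = {}
    for sid, q in means.items():
        head = rot.from_axis_angle(_AXES["Z"], -yaws[sid])
        # neutral segment frames are the identity, so the heading-corrected
        # neutral orientation is itself the mounting offset
        offsets[sid] = rot.qmul(head, q)
    return RegistrationResult(offsets, yaws, mean_heading)


def forward_kinematics(
    model: ChainModel,
    angles_deg: np.ndarray,
    pelvis_pos: np.ndarray | None = None,
    with_positions: bool = True,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Compose joint rotations root-to-leaf into segment poses.

    ``angles_deg`` has shape ``(..., n_dofs)`` in the order of
    ``model.dof_labels``.  Returns ``(orientations, positions)`` where
    orientations maps segment -> quaternion ``(..., 4)`` and positions
    maps segment origins and named tracking points -> ``(..., 3)`` m.
    Pelvis translations (``pelvis_pos``) are carried through but never
    enter the joint angles.
    """
    angles = np.radians(np.asarray(angles_deg, dtype=float))
    if angles.shape[-1] != model.n_dofs:
        raise ValueError(
            f"angle vector has {angles.shape[-1]} DOFs, model has {model.n_dofs}"
        )
    lead = angles.shape[:-1]
    labels = model.dof_labels
    idx = {d: i for i, d in enumerate(labels)}
    orient: dict[str, np.ndarray] = {"ground": rot.qidentity(lead) if lead else rot.qidentity()}
    pos: dict[str, np.ndarray] = {"ground": np.zeros(lead + (3,))}
    # inner products skip re-normalization: all factors are exactly unit up
    # to rounding, and IK evaluates this chain thousands of times
    ax_component = {"X": 1, "Y": 2, "Z": 3}
    for joint in model.joints:
        qj = None
        for d in joint.dofs:
            half = 0.5 * angles[..., idx[d]]
            qd = np.zeros(lead + (4,))
            qd[..., 0] = np.cos(half)
            qd[..., ax_component[_DOF_AXIS[d.rsplit("_", 1)[-1]]]] = np.sin(half)
            qj = qd if qj is None else rot._mul_raw(qj, qd)
        qp = orient[joint.parent]
        orient[joint.child] = rot._mul_raw(qp, qj)
        if with_positions:
            off = model.geometry.get(joint.child)
            if off is not None:
                pos[joint.child] = pos[joint.parent] + rot.qrotate(qp, off)
            else:
                pos[joint.child] = pos[joint.parent]
    if not with_positions:
        del orient["ground"]
        return orient, {}
    if pelvis_pos is not None:
        shift = np.asarray(pelvis_pos, dtype=float) - model.geometry.get(
            "pelvis", np.zeros(3)
        )
        for s in pos:
            pos[s] = pos[s] + shift
    for name, (seg, off) in model.points.items():
        pos[name] = pos[seg] + rot.qrotate(orient[seg], off)
    del orient["ground"], pos["ground"]
    return orient, pos


_CONJ = np.array([1.0, -1.0, -1.0, -1.0])


def _rotvec_fast(q):
    # log map for near-unit quaternions, sign-invariant, no canonicalization
    w = q[..., 0]
    v = q[..., 1:]
    n = np.sqrt(np.sum(v * v, axis=-1))
    ang = 2.0 * np.arctan2(n, np.abs(w))
    scale = np.where(w < 0, -1.0, 1.0) * ang / np.maximum(n, 1e-300)
    return v * scale[..., None]


def _decompose_init(model: ChainModel, targets: dict) -> np.ndarray:
    """Closed-form initial angles from per-joint Euler decomposition.

    When every segment is observed, the relative parent-child rotations
    decompose directly into the joint's intrinsic FE(Y)-AA(X)-IE(Z)
    angles; for joints with fewer DOFs the unmodelled components are
    dropped (geodesic projection about Y for pure-flexion joints).  For
    self-consistent targets this is already the IK optimum; the
    Gauss-Newton refinement then mops up inconsistencies.
    """
    n = next(iter(targets.values())).shape[0]
    nd = model.n_dofs
    labels = model.dof_labels
    idx = {d: i for i, d in enumerate(labels)}
    out = np.zeros((n, nd))
    have = {"ground": rot.qidentity((n,))}
    for joint in model.joints:
        parent_q = have.get(joint.parent)
        child_q = targets.get(joint.child)
        if parent_q is None or child_q is None:
            have[joint.child] = None if child_q is None else child_q
            continue
        have[joint.child] = child_q
        qrel = rot._mul_raw(parent_q * _CONJ, child_q)
        ndof = len(joint.dofs)
        if ndof == 1:
            # geodesic projection onto the Y-axis circle subgroup
            ang = 2.0 * np.arctan2(qrel[..., 2], qrel[..., 0])
            out[:, idx[joint.dofs[0]]] = np.degrees(ang)
            continue
        m = rot.to_matrix(qrel)
        b = np.arcsin(np.clip(-m[..., 1, 2], -1.0, 1.0))  # AA about X
        a = np.arctan2(m[..., 0, 2], m[..., 2, 2])  # FE about Y
        out[:, idx[joint.dofs[0]]] = np.degrees(a)
        out[:, idx[joint.dofs[1]]] = np.degrees(b)
        if ndof == 3:
            c = np.arctan2(m[..., 1, 0], m[..., 1, 1])  # IE about Z
            out[:, idx[joint.dofs[2]]] = np.degrees(c)
    return out


def _residuals(model, angles_deg, targets, wsqrt):
    orient, _ = forward_kinematics(model, angles_deg, with_positions=False)
    res = [
        wsqrt[s] * _rotvec_fast(rot._mul_raw(targets[s] * _CONJ, orient[s]))
        for s in targets
    ]
    return np.concatenate(res, axis=-1)


def ik_orientation(
    model: ChainModel,
    targets: dict[str, np.ndarray],
    weights: dict[str, float] | None = None,
    t: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    init_deg: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Orientation-tracking inverse kinematics.

    Per frame, finds the joint-angle vector minimizing the weighted sum of
    squared geodesic (axis-angle) differences between the model's forward
    kinematics and the target segment orientations.  Solved by damped
    Gauss-Newton on the rotation-vector residuals with a numeric Jacobian,
    batched over frames; iterations stop when the objective gradient falls
    below ``tol`` (rad) or after ``max_iter`` iterations.  Frames that do
    not converge keep their last iterate and are flagged.

    Returns ``(angles_deg of shape (n, n_dofs), converged mask)``.
    """
    segs = list(targets)
    tq = {s: np.atleast_2d(np.asarray(targets[s], dtype=float)) for s in segs}
    n = tq[segs[0]].shape[0]
    if any(tq[s].shape != (n, 4) for s in segs):
        raise ValueError("all targets must be (n, 4) with a common n")
    weights = weights or {}
    wsqrt = {s: np.sqrt(float(weights.get(s, 1.0))) for s in segs}
    nd = model.n_dofs

    if init_deg is None:
        x = _decompose_init(model, tq)
    else:
        x = np.array(init_deg, dtype=float, ndmin=2) * np.ones((n, nd))
    r = _residuals(model, x, tq, wsqrt)
    obj = 0.5 * np.sum(r**2, axis=-1)
    active = np.ones(n, dtype=bool)
    converged = np.zeros(n, dtype=bool)
    # Jacobian step in degrees; residuals are radians.  The Jacobian varies
    # slowly with the angles, so it is refreshed only every few iterations
    # (chord Gauss-Newton); convergence is declared only against a fresh one.
    h = 1e-4
    lam = 1e-9
    jac_refresh = 3
    J_full = np.zeros((n, 3 * len(segs), nd))
    age = np.full(n, jac_refresh)
    for _ in range(max_iter):
        ia = np.flatnonzero(active)
        if ia.size == 0:
            break
        xa, ra = x[ia], r[ia]
        stale = age[ia] >= jac_refresh
        if np.any(stale):
            ist = ia[stale]
            xs, rs = x[ist], r[ist]
            tqs = {s: tq[s][ist] for s in segs}
            Jn = np.empty((ist.size, rs.shape[-1], nd))
            for j in range(nd):
                xp = xs.copy()
                xp[:, j] += h
                Jn[:, :, j] = (_residuals(model, xp, tqs, wsqrt) - rs) / h
            J_full[ist] = Jn
            age[ist] = 0
        J = J_full[ia]
        g = np.einsum("nrj,nr->nj", J, ra)  # objective gradient (per deg)
        # the Jacobian is at most jac_refresh small steps old, so the
        # gradient it yields is accurate enough to test convergence
        grad_ok = np.max(np.abs(np.radians(g)), axis=-1) < tol
        Jt = np.swapaxes(J, 1, 2)
        JtJ = Jt @ J
        JtJ[:, np.arange(nd), np.arange(nd)] += lam
        try:
            step = -np.linalg.solve(JtJ, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = -np.linalg.lstsq(
                J.reshape(-1, nd), ra.reshape(-1), rcond=None
            )[0][None, :] * np.ones((ia.size, 1))
        # backtracking line search keeps the objective non-increasing
        alpha = np.ones(ia.size)
        new_x = xa + step
        new_r = _residuals(model, new_x, {s: tq[s][ia] for s in segs}, wsqrt)
        new_obj = 0.5 * np.sum(new_r**2, axis=-1)
        for _bt in range(12):
            worse = new_obj > obj[ia] * (1 + 1e-14) + 1e-300
            if not np.any(worse):
                break
            alpha[worse] *= 0.5
            new_x[worse] = xa[worse] + alpha[worse, None] * step[worse]
            sub = _residuals(
                model, new_x[worse], {s: tq[s][ia][worse] for s in segs}, wsqrt
            )
            new_r[worse] = sub
            new_obj[worse] = 0.5 * np.sum(sub**2, axis=-1)
        improved = new_obj <= obj[ia]
        # a rejected step with a stale Jacobian forces a refresh, not a stop
        retry = ~improved & (age[ia] > 0)
        age[ia[retry]] = jac_refresh
        upd = ia[improved]
        x[upd], r[upd] = new_x[improved], new_r[improved]
        obj[upd] = new_obj[improved]
        age[upd] += 1
        done = grad_ok | (~improved & ~retry)
        converged[ia[grad_ok]] = True
        active[ia[done]] = False
    # frames stopped by the iteration cap keep their last iterate
    return x, converged


def segment_orientation_from_markers(
    traj: MarkerTrajectories,
) -> dict[str, OrientationTrack]:
    """Per-frame least-squares rigid orientation of each marker cluster.

    Solves the orthogonal Procrustes problem (Kabsch, SVD) mapping the
    cluster template to the measured marker positions, with the
    determinant constrained to +1 (proper rotation).  Requires >= 3
    non-collinear markers per segment.
    """
    out = {}
    n = len(traj.t)
    for seg, template in traj.templates.items():
        mids = [m for m in template if m in traj.positions]
        if len(mids) < 3:
            raise ValueError(f"segment {seg} has fewer than 3 markers")
        P = np.stack([np.asarray(template[m], dtype=float) for m in mids])
        Pc = P - P.mean(axis=0)
        sv = np.linalg.svd(Pc, compute_uv=False)
        if sv[1] < 1e-9 * max(sv[0], 1.0):
            raise ValueError(f"degenerate (collinear) cluster geometry on {seg}")
        Q = np.stack([traj.positions[m] for m in mids], axis=1)  # (n, k, 3)
        Qc = Q - Q.mean(axis=1, keepdims=True)
        H = np.einsum("ka,nkb->nab", Pc, Qc)  # (n, 3, 3)
        U, _, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(np.einsum("nab,nbc->nac", np.transpose(Vt, (0, 2, 1)), np.transpose(U, (0, 2, 1)))))
        D = np.zeros((n, 3, 3))
        D[:, 0, 0] = 1.0
        D[:, 1, 1] = 1.0
        D[:, 2, 2] = d
        R = np.einsum("nab,nbc,ncd->nad", np.transpose(Vt, (0, 2, 1)), D, np.transpose(U, (0, 2, 1)))
        out[seg] = OrientationTrack(seg, np.asarray(traj.t, float).copy(), rot.from_matrix(R))
    return out


def pose_offset_alignment(
    ref: JointAngleSeries,
    imu: JointAngleSeries,
    neutral_window: tuple[float, float] = (0.0, 1.0),
) -> JointAngleSeries:
    """Shift the reference series by per-DOF constants to match the IMU
    model's neutral standing pose.

    The offset for each DOF is the difference of the two series' means
    over ``neutral_window`` (both series observing the same neutral
    pose); it is subtracted from the reference series.  Constant shifts
    leave every variability outcome except the angle mean untouched.
    """
    if ref.labels != imu.labels:
        raise ValueError("series have different DOF labels")
    wr = (ref.t >= neutral_window[0]) & (ref.t <= neutral_window[1])
    wi = (imu.t >= neutral_window[0]) & (imu.t <= neutral_window[1])
    if not (np.any(wr) and np.any(wi)):
        raise ValueError("neutral window contains no samples")
    offset = ref.angles[wr].mean(axis=0) - imu.angles[wi].mean(axis=0)
    return JointAngleSeries(ref.t.copy(), ref.angles - offset, list(ref.labels))


# ---------------------------------------------------------------------------
# file I/O: STO-dialect quaternion tables and marker CSV

def write_quaternion_table(path, t: np.ndarray, tracks: dict[str, np.ndarray]) -> None:
    """Write segment orientations as a tab-delimited quaternion table.

    One ``time`` column plus one column per segment whose cells are
    ``w,x,y,z`` (comma-joined, scalar-first) — the dialect used by
    orientation-tracking toolchains.
    """
    names = list(tracks)
    with open(path, "w") as f:
        f.write("DataRate=auto\nOrientationOrder=w,x,y,z\nendheader\n")
        f.write("\t".join(["time"] + names) + "\n")
        for i, ti in enumerate(np.asarray(t, dtype=float)):
            cells = [f"{ti:.8f}"]
            for s in names:
                q = tracks[s][i]
                cells.append(",".join(f"{c:.10f}" for c in q))
            f.write("\t".join(cells) + "\n")


def read_quaternion_table(path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Read a quaternion table written by :func:`write_quaternion_table`."""
    with open(path) as f:
        lines = f.read().splitlines()
    try:
        start = lines.index("endheader") + 1
    except ValueError:
        start = 0
    header = lines[start].split("\t")
    names = header[1:]
    t = []
    data = {s: [] for s in names}
    for line in lines[start + 1:]:
        if not line.strip():
            continue
        cells = line.split("\t")
        t.append(float(cells[0]))
        for s, c in zip(names, cells[1:]):
            data[s].append([float(v) for v in c.split(",")])
    return np.array(t), {s: rot.qcanonical(np.array(v)) for s, v in data.items()}


def write_markers_csv(path, traj: MarkerTrajectories) -> None:
    """Write marker trajectories as long CSV: ``t, marker_id, x, y, z`` (mm)."""
    import pandas as pd

    frames = []
    for mid, p in traj.positions.items():
        frames.append(
            pd.DataFrame({"t": traj.t, "marker_id": mid,
                          "x": p[:, 0], "y": p[:, 1], "z": p[:, 2]})
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_markers_csv(
    path,
    marker_segments: dict[str, str],
    templates: dict[str, dict[str, np.ndarray]],
) -> MarkerTrajectories:
    """Read long-format marker CSV into :class:`MarkerTrajectories`."""
    import pandas as pd

    df = pd.read_csv(path)
    positions = {}
    t = None
    for mid, g in df.groupby("marker_id", sort=False):
        if t is None:
            t = g["t"].to_numpy()
        positions[str(mid)] = g[["x", "y", "z"]].to_numpy()
    return MarkerTrajectories(t, positions, marker_segments, templates)
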