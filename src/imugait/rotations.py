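"""Quaternion and rotation primitives.

Conventions used throughout the package
---------------------------------------
* Quaternions are numpy arrays of shape ``(..., 4)`` in **scalar-first**
  order ``(w, x, y, z)`` and represent rotations via the Hamilton product
  (right-handed, active rotations).
* Every exported operation returns unit quaternions canonicalized to
  ``w >= 0``.  ``q`` and ``-q`` encode the same rotation (double cover);
  all distance functions are sign-invariant.
* Euler angles follow the intrinsic Z-Y-X sequence (yaw, pitch, roll) in
  radians; the rotation matrix is ``Rz(yaw) @ Ry(pitch) @ Rx(roll)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "GimbalLockError",
    "qidentity",
    "qnormalize",
    "qcanonical",
    "qmul",
    "qconj",
    "qrotate",
    "from_axis_angle",
    "to_axis_angle",
    "from_rotvec",
    "to_rotvec",
    "geodesic_angle",
    "euler_zyx",
    "from_euler_zyx",
    "to_matrix",
    "from_matrix",
]

#: pitch values closer than this to +/- pi/2 are flagged as gimbal lock
GIMBAL_LOCK_TOL = 1e-6


class GimbalLockError(ValueError):
    """Raised when an Euler-domain operation hits a gimbal-locked sample."""

    def __init__(self, indices):
        self.indices = np.atleast_1d(indices)
        super().__init__(
            f"gimbal lock (|pitch| ~ pi/2) at sample index {self.indices[0]}"
            + (f" (+{self.indices.size - 1} more)" if self.indices.size > 1 else "")
        )


def qidentity(shape=()) -> np.ndarray:
    """Identity quaternion(s) of the given leading shape."""
    q = np.zeros(tuple(np.atleast_1d(shape)) + (4,)) if shape else np.zeros(4)
    q[..., 0] = 1.0
    return q


def qnormalize(q: np.ndarray) -> np.ndarray:
    """Normalize to unit length.  Raises on non-finite or zero-norm input."""
    q = np.asarray(q, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("non-finite quaternion input")
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n == 0):
        raise ValueError("zero-norm quaternion")
    return q / n


def qcanonical(q: np.ndarray) -> np.ndarray:
    """Flip sign so that w >= 0 (fixes the double-cover representative)."""
    q = np.asarray(q, dtype=float)
    return np.where(q[..., :1] < 0, -q, q)


def _unit(q: np.ndarray) -> np.ndarray:
    return qcanonical(qnormalize(q))


def _mul_raw(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product without normalization/canonicalization (internal
    fast path for chains of already-unit quaternions)."""
    w1, x1, y1, z1 = (q1[..., i] for i in range(4))
    w2, x2, y2, z2 = (q2[..., i] for i in range(4))
    out = np.empty(np.broadcast(q1, q2).shape)
    out[..., 0] = w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2
    out[..., 1] = w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2
    out[..., 2] = w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2
    out[..., 3] = w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2
    return out


def qmul(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product ``q1 * q2`` (apply q2 first, then q1), broadcasting."""
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    return _unit(_mul_raw(q1, q2))


def qconj(q: np.ndarray) -> np.ndarray:
    """Conjugate (= inverse for unit quaternions)."""
    q = np.asarray(q, dtype=float)
    return qcanonical(q * np.array([1.0, -1.0, -1.0, -1.0]))


def qrotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) ``v`` by quaternion(s) ``q`` (active rotation)."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    w = q[..., :1]
    u = q[..., 1:]
    uv = np.cross(u, v)
    return v + 2.0 * (w * uv + np.cross(u, uv))


def from_axis_angle(axis: np.ndarray, angle) -> np.ndarray:
    """Quaternion for a rotation of ``angle`` rad about unit ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis, axis=-1, keepdims=True)
    angle = np.asarray(angle, dtype=float)
    half = angle / 2.0
    q = np.empty(np.broadcast(axis[..., 0], angle).shape + (4,))
    q[..., 0] = np.cos(half)
    q[..., 1:] = np.sin(half)[..., None] * axis
    return _unit(q)


def to_axis_angle(q: np.ndarray):
    """Decompose into (unit axis, angle in [0, pi]).

    The identity rotation returns axis (1, 0, 0) and angle 0.
    """
    q = _unit(q)
    vec = q[..., 1:]
    n = np.linalg.norm(vec, axis=-1)
    angle = 2.0 * np.arctan2(n, q[..., 0])
    safe = np.where(n > 0, n, 1.0)[..., None]
    axis = np.where(n[..., None] > 0, vec / safe, np.array([1.0, 0.0, 0.0]))
    return axis, angle


def from_rotvec(rv: np.ndarray) -> np.ndarray:
    """Exponential map: rotation vector (axis * angle, rad) -> quaternion."""
    rv = np.asarray(rv, dtype=float)
    angle = np.linalg.norm(rv, axis=-1)
    half = angle / 2.0
    # sinc-based form is stable at angle -> 0
    k = 0.5 * np.sinc(half / np.pi)
    q = np.empty(rv.shape[:-1] + (4,))
    q[..., 0] = np.cos(half)
    q[..., 1:] = k[..., None] * rv
    return _unit(q)


def to_rotvec(q: np.ndarray) -> np.ndarray:
    """Logarithm map: quaternion -> rotation vector (axis * angle, rad)."""
    axis, angle = to_axis_angle(q)
    return axis * angle[..., None]


def geodesic_angle(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Angle in [0, pi] of the relative rotation between q1 and q2.

    Sign-invariant: ``geodesic_angle(q, -q) == 0``.  Equal to
    ``2 * acos(|<q1, q2>|)`` but evaluated through the relative rotation
    with atan2, which keeps full precision for near-identical rotations.
    """
    q1 = qnormalize(q1)
    q2 = qnormalize(q2)
    qr = qmul(qconj(q1), q2)
    return 2.0 * np.arctan2(np.linalg.norm(qr[..., 1:], axis=-1), np.abs(qr[..., 0]))


def to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix (..., 3, 3) of the quaternion."""
    q = qnormalize(q)
    w, x, y, z = (q[..., i] for i in range(4))
    m = np.empty(q.shape[:-1] + (3, 3))
    m[..., 0, 0] = 1 - 2 * (y * y + z * z)
    m[..., 0, 1] = 2 * (x * y - w * z)
    m[..., 0, 2] = 2 * (x * z + w * y)
    m[..., 1, 0] = 2 * (x * y + w * z)
    m[..., 1, 1] = 1 - 2 * (x * x + z * z)
    m[..., 1, 2] = 2 * (y * z - w * x)
    m[..., 2, 0] = 2 * (x * z - w * y)
    m[..., 2, 1] = 2 * (y * z + w * x)
    m[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return m


def from_matrix(m: np.ndarray) -> np.ndarray:
    """Quaternion from rotation matrix (..., 3, 3); Shepperd's method."""
    m = np.asarray(m, dtype=float)
    # delegate the numerically careful branch selection to scipy's algorithm
    # via a compact vectorized variant
    tr = m[..., 0, 0] + m[..., 1, 1] + m[..., 2, 2]
    q = np.empty(m.shape[:-2] + (4,))
    # four candidate constructions; pick the one with the largest pivot
    cand = np.stack(
        [tr, m[..., 0, 0], m[..., 1, 1], m[..., 2, 2]], axis=-1
    )
    choice = np.argmax(cand, axis=-1)

    def _fill(mask, i):
        if not np.any(mask):
            return
        mm = m[mask]
        if i == 0:
            s = np.sqrt(1.0 + tr[mask]) * 2
            q[mask, 0] = 0.25 * s
            q[mask, 1] = (mm[..., 2, 1] - mm[..., 1, 2]) / s
            q[mask, 2] = (mm[..., 0, 2] - mm[..., 2, 0]) / s
            q[mask, 3] = (mm[..., 1, 0] - mm[..., 0, 1]) / s
        elif i == 1:
            s = np.sqrt(1.0 + mm[..., 0, 0] - mm[..., 1, 1] - mm[..., 2, 2]) * 2
            q[mask, 0] = (mm[..., 2, 1] - mm[..., 1, 2]) / s
            q[mask, 1] = 0.25 * s
            q[mask, 2] = (mm[..., 0, 1] + mm[..., 1, 0]) / s
            q[mask, 3] = (mm[..., 0, 2] + mm[..., 2, 0]) / s
        elif i == 2:
            s = np.sqrt(1.0 - mm[..., 0, 0] + mm[..., 1, 1] - mm[..., 2, 2]) * 2
            q[mask, 0] = (mm[..., 0, 2] - mm[..., 2, 0]) / s
            q[mask, 1] = (mm[..., 0, 1] + mm[..., 1, 0]) / s
            q[mask, 2] = 0.25 * s
            q[mask, 3] = (mm[..., 1, 2] + mm[..., 2, 1]) / s
        else:
            s = np.sqrt(1.0 - mm[..., 0, 0] - mm[..., 1, 1] + mm[..., 2, 2]) * 2
            q[mask, 0] = (mm[..., 1, 0] - mm[..., 0, 1]) / s
            q[mask, 1] = (mm[..., 0, 2] + mm[..., 2, 0]) / s
            q[mask, 2] = (mm[..., 1, 2] + mm[..., 2, 1]) / s
            q[mask, 3] = 0.25 * s

    scalar_input = q.ndim == 1
    if scalar_input:
        q = q[None]
        m = m[None]
        tr = np.atleast_1d(tr)
        choice = np.atleast_1d(choice)
    for i in range(4):
        _fill(choice == i, i)
    q = _unit(q)
    return q[0] if scalar_input else q


def euler_zyx(q: np.ndarray, raise_on_lock: bool = False):
    """Intrinsic Z-Y-X Euler angles (yaw, pitch, roll), plus a lock mask.

    Returns ``(angles, lock)`` where ``angles`` has shape ``(..., 3)`` in
    the order yaw, pitch, roll (rad) and ``lock`` flags samples whose
    pitch is within ``GIMBAL_LOCK_TOL`` of +/- pi/2.  If ``raise_on_lock``
    a :class:`GimbalLockError` carrying the offending indices is raised.
    """
    q = qnormalize(q)
    w, x, y, z = (q[..., i] for i in range(4))
    # elements of the rotation matrix needed for ZYX extraction
    r20 = 2 * (x * z - w * y)
    s = np.clip(-r20, -1.0, 1.0)
    pitch = np.arcsin(s)
    lock = np.abs(np.abs(s) - 1.0) < GIMBAL_LOCK_TOL
    if raise_on_lock and np.any(lock):
        raise GimbalLockError(np.flatnonzero(np.atleast_1d(lock)))
    yaw = np.arctan2(2 * (x * y + w * z), 1 - 2 * (y * y + z * z))
    roll = np.arctan2(2 * (y * z + w * x), 1 - 2 * (x * x + y * y))
    return np.stack([yaw, pitch, roll], axis=-1), lock


def from_euler_zyx(angles: np.ndarray) -> np.ndarray:
    """Quaternion from intrinsic Z-Y-X (yaw, pitch, roll) angles in rad."""
    angles = np.asarray(angles, dtype=float)
    half = angles / 2.0
    cy, cp, cr = np.cos(half[..., 0]), np.cos(half[..., 1]), np.cos(half[..., 2])
    sy, sp, sr = np.sin(half[..., 0]), np.sin(half[..., 1]), np.sin(half[..., 2])
    q = np.empty(angles.shape[:-1] + (4,))
    q[..., 0] = cy * cp * cr + sy * sp * sr
    q[..., 1] = cy * cp * sr - sy * sp * cr
    q[..., 2] = cy * sp * cr + sy * cp * sr
    q[..., 3] = sy * cp * cr - cy * sp * sr
    return _unit(q)
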