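"""Heel-strike detection, stride partitioning and time normalization.

Strides are delimited by heel strikes found on the Euclidean norm of the
foot (calcaneus) linear velocity: after zero-lag low-pass filtering, each
local maximum of the speed (mid-swing) is followed by the local minimum
taken as foot contact.  After a steady-state discard window the next
``n_strides`` strides are kept; each is resampled to 101 points (0-100%
of the gait cycle) by linear interpolation, and the untouched
concatenated samples over the same span are retained as the companion
continuous series for the state-space metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .kinematics import JointAngleSeries

__all__ = [
    "StrideSet",
    "StrideMatrix",
    "lowpass_zero_lag",
    "detect_heel_strikes",
    "extract_strides",
]

#: local maxima of foot speed must be at least this fraction of the
#: signal range prominent to count as a swing peak.  The mid-swing peak
#: has prominence near 100% of the range; secondary stance/toe-off bumps
#: stay below ~20%, so 25% separates them with margin on both sides.
PROMINENCE_FRAC = 0.25

#: events closer than this fraction of the median stride time are merged
MIN_SEPARATION_FRAC = 0.4


@dataclass
class StrideSet:
    """Heel-strike events of one foot."""

    indices: np.ndarray  # sample indices, strictly increasing
    times: np.ndarray  # s
    fs: float

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.indices) <= 0):
            raise ValueError("event indices must be strictly increasing")

    @property
    def n_strides(self) -> int:
        return max(len(self.indices) - 1, 0)

    @property
    def durations(self) -> np.ndarray:
        return np.diff(self.times)

    def to_frame(self, foot: str = ""):
        import pandas as pd

        return pd.DataFrame(
            {"foot": foot, "index": self.indices, "time_s": self.times}
        )


@dataclass
class StrideMatrix:
    """Time-normalized strides plus the companion continuous series.

    ``data`` is (n_strides, 101, n_dofs) in degrees; ``continuous`` is the
    raw concatenated series over the same strides, used for the
    state-space metrics that must not be distorted by per-stride
    resampling.
    """

    data: np.ndarray
    labels: list[str]
    continuous: np.ndarray  # (m, n_dofs)
    fs: float  # sampling rate of the continuous series
    durations: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1] != 101:
            raise ValueError("stride matrix must be (n_strides, 101, n_dofs)")

    @property
    def n_strides(self) -> int:
        return self.data.shape[0]

    def dof(self, label: str) -> np.ndarray:
        return self.data[:, :, self.labels.index(label)]

    def continuous_dof(self, label: str) -> np.ndarray:
        return self.continuous[:, self.labels.index(label)]

    def to_frame(self):
        import pandas as pd

        n, _, nd = self.data.shape
        stride, pct, dof = np.meshgrid(
            np.arange(n), np.arange(101), np.arange(nd), indexing="ij"
        )
        return pd.DataFrame(
            {
                "stride": stride.ravel(),
                "pct": pct.ravel(),
                "dof": np.asarray(self.labels)[dof.ravel()],
                "angle_deg": self.data.ravel(),
            }
        )


def lowpass_zero_lag(
    x: np.ndarray, fs: float, cutoff: float = 10.0, order: int = 4
) -> np.ndarray:
    """Zero-lag low-pass Butterworth filter (forward-backward).

    ``order`` is the net order: a filter of order ``order // 2`` is applied
    forward and backward (filtfilt), doubling the attenuation while
    cancelling the phase shift.
    """
    if fs <= 2 * cutoff:
        raise ValueError("sampling rate must exceed twice the cutoff")
    if order % 2:
        raise ValueError("net order must be even (forward-backward passes)")
    sos = signal.butter(order // 2, cutoff, fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)


def detect_heel_strikes(
    foot_velocity: np.ndarray,
    fs: float,
    prominence_frac: float = PROMINENCE_FRAC,
    min_separation_frac: float = MIN_SEPARATION_FRAC,
) -> StrideSet:
    """Heel strikes from the norm of the foot linear velocity.

    ``foot_velocity`` is (n, 3) m/s (already low-pass filtered) or an
    (n,) precomputed speed.  For every local maximum of the speed whose
    prominence exceeds ``prominence_frac`` of the speed range, the first
    subsequent local minimum is an event; events closer than
    ``min_separation_frac`` of the median stride time to their
    predecessor are discarded.
    """
    v = np.asarray(foot_velocity, dtype=float)
    speed = np.linalg.norm(v, axis=1) if v.ndim == 2 else v
    rng = float(speed.max() - speed.min())
    if rng <= 0:
        raise ValueError("constant velocity: no gait events")
    peaks, _ = signal.find_peaks(speed, prominence=prominence_frac * rng)
    minima, _ = signal.find_peaks(-speed)
    events = []
    for p in peaks:
        after = minima[minima > p]
        if after.size:
            events.append(int(after[0]))
    events = np.unique(events)
    if events.size >= 3:
        med = float(np.median(np.diff(events)))
        kept = [int(events[0])]
        for e in events[1:]:
            if e - kept[-1] >= min_separation_frac * med:
                kept.append(int(e))
        events = np.asarray(kept)
    if events.size < 2:
        raise ValueError(f"found {events.size} heel strikes; need at least 2")
    return StrideSet(events, events / fs, fs)


def extract_strides(
    angles: JointAngleSeries,
    events: StrideSet,
    discard_s: float = 30.0,
    n_strides: int = 200,
) -> StrideMatrix:
    """Build the stride matrix for outcome computation.

    Heel strikes within ``discard_s`` of the start of the series are
    dropped (gait not yet at steady state); the next ``n_strides`` strides
    are kept.  Each stride is linearly resampled to 101 points over
    normalized time 0-100%; the companion continuous series is the raw
    concatenation of samples spanning the same strides.
    """
    # event indices refer to samples of the angle series they were
    # detected on; times are taken from the series clock
    ev_t = angles.t[events.indices]
    t0 = angles.t[0] + discard_s
    keep = np.flatnonzero(ev_t >= t0)
    if keep.size < n_strides + 1:
        raise ValueError(
            f"insufficient strides after discard: have {max(keep.size - 1, 0)}, "
            f"need {n_strides}"
        )
    keep = keep[: n_strides + 1]
    ev_idx = events.indices[keep]
    ev_time = ev_t[keep]
    nd = angles.angles.shape[1]
    out = np.empty((n_strides, 101, nd))
    pct = np.linspace(0.0, 1.0, 101)
    for i in range(n_strides):
        ta, tb = ev_time[i], ev_time[i + 1]
        ts = ta + pct * (tb - ta)
        for j in range(nd):
            out[i, :, j] = np.interp(ts, angles.t, angles.angles[:, j])
    continuous = angles.angles[ev_idx[0]: ev_idx[-1] + 1]
    return StrideMatrix(
        out, list(angles.labels), continuous, angles.fs, np.diff(ev_time)
    )
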