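"""Stride-to-stride motor-variability outcomes.

Five outcomes are computed per degree of freedom:

* **ROM** — per-stride range of motion (max - min of the 101-point
  normalized stride), averaged across strides (deg).
* **meanSD** — across-stride standard deviation at each of the 101 cycle
  points, averaged over the cycle (deg); the magnitude of variability.
* **lambda_max** — local divergence exponent (Rosenstein): the continuous
  series is resampled to a fixed number of points (100 per stride on
  average), delay-embedded, and the mean log divergence of nearest
  neighbours is tracked; the slope over the first half stride, expressed
  per stride, measures local dynamic stability (higher = less stable).
* **dfa_alpha** — detrended fluctuation analysis scaling exponent of the
  per-stride ROM series; ~0.5 for uncorrelated fluctuations, >0.5 for
  statistically persistent ones.
* **saen** — multiscale sample entropy of the continuous series (at
  120 Hz), template length m=2, tolerance 0.15 x SD, coarse-graining
  scale 4; lower values mean a more regular signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .gait_events import StrideMatrix

__all__ = [
    "EmbeddingParams",
    "OutcomeTable",
    "OUTCOME_NAMES",
    "rom_per_stride",
    "mean_sd",
    "lambda_max",
    "dfa_alpha",
    "multiscale_sample_entropy",
    "compute_outcomes",
]

OUTCOME_NAMES = ("ROM", "meanSD", "lambda_max", "dfa_alpha", "saen")


@dataclass
class EmbeddingParams:
    """State-space reconstruction settings for the divergence exponent.

    Defaults: the continuous series is normalized to 20,000 points (100
    per stride for 200 strides), embedded in 5 dimensions at a lag of 10
    points, and the divergence slope is fit from 0 to 0.5 strides (50
    points).  The Theiler exclusion window for the nearest-neighbour
    search is one mean period (``points_per_stride``).
    """

    n_points: int = 20000
    dims: int = 5
    lag: int = 10
    fit_points: int = 50
    points_per_stride: int = 100


@dataclass
class OutcomeTable:
    """Per-DOF outcome values as a tidy DataFrame wrapper."""

    values: "object"  # pandas DataFrame: index dof, columns OUTCOME_NAMES

    def __post_init__(self):
        bad = []
        for c in ("ROM", "meanSD", "dfa_alpha", "saen"):
            if c in self.values.columns and (self.values[c] < 0).any():
                bad.append(c)
        if bad:
            raise ValueError(f"negative values in non-negative outcomes: {bad}")

    def to_long(self):
        import pandas as pd

        long = self.values.reset_index().melt(
            id_vars="dof", var_name="outcome", value_name="value"
        )
        return pd.DataFrame(long)

    def to_csv(self, path):
        self.to_long().to_csv(path, index=False)


def rom_per_stride(m: StrideMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-stride ROM (max - min over the 101 points) and its mean.

    Returns ``(rom of shape (n_strides, n_dofs), mean of shape (n_dofs,))``.
    """
    if m.n_strides < 1:
        raise ValueError("need at least one stride")
    rom = m.data.max(axis=1) - m.data.min(axis=1)
    return rom, rom.mean(axis=0)


def mean_sd(m: StrideMatrix) -> np.ndarray:
    """Across-stride sample SD at each cycle point, averaged over points."""
    if m.n_strides < 2:
        raise ValueError("need at least two strides")
    return m.data.std(axis=0, ddof=1).mean(axis=0)


def _resample(x: np.ndarray, n: int) -> np.ndarray:
    old = np.linspace(0.0, 1.0, len(x))
    return np.interp(np.linspace(0.0, 1.0, n), old, x)


def lambda_max(
    continuous: np.ndarray,
    params: EmbeddingParams | None = None,
) -> float:
    """Largest finite-time divergence exponent, Rosenstein's method.

    The series is amplitude-agnostic (slope of a log divergence curve).
    For each delay-embedded point, the nearest neighbour outside a
    temporal exclusion window of one mean period is found; the mean log
    Euclidean separation of such pairs is tracked over
    ``params.fit_points`` steps and its least-squares slope, multiplied
    by ``points_per_stride``, is returned in units of 1/stride.
    """
    p = params or EmbeddingParams()
    x = np.asarray(continuous, dtype=float)
    if x.ndim != 1:
        raise ValueError("continuous series must be 1-D")
    x = _resample(x, p.n_points)
    span = (p.dims - 1) * p.lag
    if p.n_points <= span + p.fit_points + 1:
        raise ValueError("series too short for the embedding and fit window")
    n_emb = p.n_points - span
    emb = np.lib.stride_tricks.sliding_window_view(x, span + 1)[:, :: p.lag]
    assert emb.shape == (n_emb, p.dims)
    # nearest neighbour with Theiler window: query enough candidates that
    # at least one falls outside the exclusion zone
    w = p.points_per_stride
    tree = cKDTree(emb)
    # staged query: most points find a neighbour outside the Theiler
    # window among their ~32 nearest; only the rest need the full 2w+2
    nn = np.empty(n_emb, dtype=int)
    pending = np.arange(n_emb)
    k = min(32, n_emb)
    while pending.size:
        _, idx = tree.query(emb[pending], k=k)
        idx = np.atleast_2d(idx)
        valid = np.abs(idx - pending[:, None]) > w
        found = valid.any(axis=1)
        first = np.argmax(valid, axis=1)
        nn[pending[found]] = idx[np.arange(len(pending)), first][found]
        pending = pending[~found]
        if k >= min(2 * w + 2, n_emb):
            if pending.size:
                raise ValueError(
                    "no neighbour outside the Theiler window; series too short"
                )
            break
        k = min(max(2 * w + 2, k * 4), n_emb)
    # track divergence while both trajectories remain inside the series
    steps = p.fit_points + 1
    last = n_emb - steps
    i0 = np.arange(n_emb)
    ok = (i0 <= last) & (nn <= last)
    a, b = i0[ok], nn[ok]
    logd = np.empty((steps, a.size))
    for s in range(steps):
        d = np.linalg.norm(emb[a + s] - emb[b + s], axis=1)
        logd[s] = np.log(np.maximum(d, 1e-300))
    curve = logd.mean(axis=1)
    slope = np.polyfit(np.arange(steps), curve, 1)[0]
    return float(slope * p.points_per_stride)


def dfa_alpha(
    rom_series: np.ndarray,
    box_sizes: np.ndarray | None = None,
) -> float:
    """DFA scaling exponent of a per-stride fluctuation series.

    The mean-subtracted series is integrated; in non-overlapping boxes of
    each size the profile is linearly detrended and the RMS fluctuation
    F(n) computed; alpha is the slope of log F(n) vs log n over 16
    log-spaced box sizes from 4 to N/4.
    """
    x = np.asarray(rom_series, dtype=float)
    n = len(x)
    if n < 64:
        raise ValueError("DFA needs at least 64 strides")
    if box_sizes is None:
        box_sizes = np.unique(
            np.round(np.geomspace(4, n // 4, 16)).astype(int)
        )
    profile = np.cumsum(x - x.mean())
    fs = []
    for s in box_sizes:
        nb = n // s
        seg = profile[: nb * s].reshape(nb, s)
        t = np.arange(s)
        # least-squares line per box via closed-form normal equations
        tm = t - t.mean()
        denom = np.sum(tm**2)
        slope = seg @ tm / denom
        inter = seg.mean(axis=1)
        resid = seg - (inter[:, None] + np.outer(slope, tm))
        fs.append(np.sqrt(np.mean(resid**2)))
    # a fluctuation-free (constant) series has F(n) = 0 at every scale;
    # flooring makes the log-log slope 0 rather than undefined
    fs = np.maximum(fs, 1e-15)
    alpha = np.polyfit(np.log(box_sizes), np.log(fs), 1)[0]
    return float(alpha)


def sample_entropy(x: np.ndarray, m: int = 2, r: float = 0.15) -> float:
    """Sample entropy: -log(A/B) with template length m and tolerance
    r x SD(x) under the Chebyshev distance, self-matches excluded.

    A constant series returns 0 (all templates match; A/B = 1).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < m + 2:
        raise ValueError("series too short for sample entropy")
    tol = r * x.std()

    def _count(mm: int) -> int:
        # number of template pairs (i < j) within tol under the Chebyshev
        # norm; both lengths use the same N - m templates so that A/B is a
        # conditional probability (and a constant series gives exactly 1)
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)[: n - m]
        tree = cKDTree(emb)
        pairs = tree.count_neighbors(tree, tol, p=np.inf)
        return (pairs - emb.shape[0]) // 2

    b = _count(m)
    a = _count(m + 1)
    if b == 0 or a == 0:
        if a == b:
            return 0.0
        raise ValueError("no template matches at length m+1 (A = 0)")
    return float(-np.log(a / b))


def multiscale_sample_entropy(
    continuous: np.ndarray,
    m: int = 2,
    r: float = 0.15,
    scale: int = 4,
) -> float:
    """Sample entropy after coarse-graining by non-overlapping means.

    ``continuous`` is the raw joint-angle series (nominally 120 Hz); it is
    averaged in non-overlapping blocks of ``scale`` samples before the
    entropy computation, following the multiscale-entropy construction.
    """
    x = np.asarray(continuous, dtype=float)
    nb = len(x) // scale
    coarse = x[: nb * scale].reshape(nb, scale).mean(axis=1)
    if len(coarse) < 200 * (m + 1):
        raise ValueError(
            f"coarse-grained series too short ({len(coarse)}); "
            f"need >= {200 * (m + 1)}"
        )
    return sample_entropy(coarse, m=m, r=r)


def compute_outcomes(
    m: StrideMatrix,
    embedding: EmbeddingParams | None = None,
    saen_m: int = 2,
    saen_r: float = 0.15,
    saen_scale: int = 4,
    saen_fs: float = 120.0,
    outcomes: tuple[str, ...] = OUTCOME_NAMES,
) -> OutcomeTable:
    """All five outcomes for every DOF of a stride matrix.

    The continuous companion series is used for ``lambda_max`` and
    ``saen``; for ``saen`` it is first resampled to ``saen_fs`` (120 Hz)
    so that IMU- and marker-path entropies share a sampling rate.
    Deterministic given its inputs.
    """
    import pandas as pd

    emb = embedding
    if emb is None:
        emb = EmbeddingParams(
            n_points=100 * m.n_strides if m.n_strides != 200 else 20000
        )
    rom, rom_mean = rom_per_stride(m)
    msd = mean_sd(m) if m.n_strides >= 2 else np.zeros(len(m.labels))
    rows = {}
    for j, label in enumerate(m.labels):
        cont = m.continuous[:, j]
        row = {}
        if "ROM" in outcomes:
            row["ROM"] = rom_mean[j]
        if "meanSD" in outcomes:
            row["meanSD"] = msd[j]
        if "lambda_max" in outcomes:
            row["lambda_max"] = lambda_max(cont, emb)
        if "dfa_alpha" in outcomes:
            row["dfa_alpha"] = dfa_alpha(rom[:, j])
        if "saen" in outcomes:
            if abs(m.fs - saen_fs) > 1e-9:
                cont_s = _resample(
                    cont, int(round(len(cont) * saen_fs / m.fs))
                )
            else:
                cont_s = cont
            row["saen"] = multiscale_sample_entropy(
                cont_s, m=saen_m, r=saen_r, scale=saen_scale
            )
        rows[label] = row
    df = pd.DataFrame(rows).T[[o for o in OUTCOME_NAMES if o in outcomes]]
    df.index.name = "dof"
    return OutcomeTable(df)
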