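"""Concurrent-validity statistics between the two measurement paths.

For joint-angle time series: mean per-stride RMSD over the 101 paired
cycle points, and its size relative to the reference range of motion
(CV_rom, %).  For scalar outcomes across analysis units (participant x
condition): ICC(2,1) — two-way random effects, absolute agreement,
single measures — with an F-based 95% CI and the conventional
poor/fair/good/excellent interpretation bands, plus Bland-Altman bias,
bias CI and 95% limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gait_events import StrideMatrix

__all__ = [
    "IccResult",
    "BlandAltmanResult",
    "timeseries_rmsd",
    "icc_2_1",
    "icc_band",
    "bland_altman",
]

#: ICC interpretation cut points: <0.40 poor, 0.40-0.59 fair,
#: 0.60-0.74 good, >=0.75 excellent
ICC_BANDS = ((0.75, "excellent"), (0.60, "good"), (0.40, "fair"))


def icc_band(icc: float) -> str:
    for cut, name in ICC_BANDS:
        if icc >= cut:
            return name
    return "poor"


@dataclass
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    band: str


@dataclass
class BlandAltmanResult:
    bias: float
    bias_ci_low: float
    bias_ci_high: float
    loa_low: float
    loa_high: float
    significant: bool  # bias 95% CI excludes zero


def timeseries_rmsd(
    ref: StrideMatrix, test: StrideMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Mean per-stride RMSD and CV_rom per DOF.

    RMSD is computed per stride across the 101 paired points and averaged
    over strides; CV_rom = 100 * RMSD / (reference mean ROM).
    Returns ``(rmsd (n_dofs,), cv_rom % (n_dofs,))``.
    """
    if ref.data.shape != test.data.shape:
        raise ValueError("stride matrices must have equal shape")
    diff = test.data - ref.data
    rmsd = np.sqrt(np.mean(diff**2, axis=1)).mean(axis=0)
    rom_ref = (ref.data.max(axis=1) - ref.data.min(axis=1)).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(rom_ref > 0, 100.0 * rmsd / rom_ref, np.nan)
    return rmsd, cv


def icc_2_1(
    ref: np.ndarray, test: np.ndarray, confidence: float = 0.95
) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single
    measures, from the two-way ANOVA mean squares.

    With n targets and k=2 raters::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    The CI follows the F-distribution construction of McGraw & Wong.
    Exchanging the raters, or adding a common constant to both, leaves
    the estimate unchanged.
    """
    y = np.column_stack([np.asarray(ref, float), np.asarray(test, float)])
    n, k = y.shape
    if n < 3:
        raise ValueError("need at least 3 analysis units")
    grand = y.mean()
    row_m = y.mean(axis=1)
    col_m = y.mean(axis=0)
    ssr = k * np.sum((row_m - grand) ** 2)
    ssc = n * np.sum((col_m - grand) ** 2)
    sse = np.sum((y - row_m[:, None] - col_m[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom > 0 else 1.0
    # F-based CI (McGraw & Wong 1996, case 2 single measures)
    alpha = 1.0 - confidence
    if mse <= 0:
        lo = hi = icc
    else:
        fj = msc / mse
        a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
        b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
        v = (a * fj + b) ** 2 / (
            a**2 * fj**2 / (k - 1) + b**2 / ((n - 1) * (k - 1))
        ) if np.isfinite(a) else (n - 1) * (k - 1)
        f_low = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_up = stats.f.ppf(1 - alpha / 2, v, n - 1)
        fo = msr / mse
        lo = n * (fo - f_low) / (
            f_low * (k * fj + k * (n - 1) - n) + n * fo
        )
        hi = n * (f_up * fo - 1) / (
            k * fj + k * (n - 1) - n + n * f_up * fo
        )
    return IccResult(float(icc), float(lo), float(hi), icc_band(float(icc)))


def bland_altman(
    ref: np.ndarray, test: np.ndarray, confidence: float = 0.95
) -> BlandAltmanResult:
    """Bland-Altman agreement of paired measurements.

    Differences are ``test - ref``; bias is their mean, the limits of
    agreement are ``bias +/- 1.96 SD(d)``, and the bias CI uses the
    t-distribution.  The bias is flagged significant when its CI
    excludes zero.
    """
    d = np.asarray(test, float) - np.asarray(ref, float)
    n = len(d)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    tcrit = stats.t.ppf(0.5 + confidence / 2, n - 1)
    half = tcrit * sd / np.sqrt(n)
    lo, hi = bias - half, bias + half
    return BlandAltmanResult(
        bias, float(lo), float(hi), float(loa_low), float(loa_high),
        bool(lo > 0 or hi < 0),
    )
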