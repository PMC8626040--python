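"""Within-participant sensitivity testing.

Each gait condition factor (speed: preferred / 70% / 130%; arm swing:
preferred / active / bound) is tested with a one-way repeated-measures
ANOVA per model, degree of freedom and outcome.  Sphericity is checked
with Mauchly's test; when violated the Greenhouse-Geisser epsilon
multiplies the numerator and denominator degrees of freedom before the
p-value lookup.  The whole family of p-values is controlled for false
discovery rate with the Benjamini-Hochberg step-up procedure, and
significant omnibus tests are followed by Bonferroni-corrected paired
comparisons of each non-preferred condition against preferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RmAnovaResult",
    "rm_anova",
    "benjamini_hochberg",
    "bonferroni_posthoc",
    "build_family",
]


@dataclass
class RmAnovaResult:
    F: float
    df_num: float
    df_den: float
    epsilon: float  # Greenhouse-Geisser epsilon (1.0 when not applied)
    mauchly_p: float
    p: float  # sphericity-corrected when Mauchly p < threshold
    partial_eta2: float
    corrected: bool


def _gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the eigenvalues of the
    double-centered covariance of the repeated measures."""
    k = cov.shape[0]
    # orthonormal contrast transformation
    c = np.linalg.qr(np.vstack([np.ones(k), np.eye(k - 1, k)]).T)[0][:, 1:]
    s = c.T @ cov @ c
    lam = np.linalg.eigvalsh(s)
    return float(lam.sum() ** 2 / ((k - 1) * np.sum(lam**2)))


def _mauchly_p(cov: np.ndarray, n: int) -> float:
    """Mauchly's sphericity test (chi-square approximation)."""
    k = cov.shape[0]
    c = np.linalg.qr(np.vstack([np.ones(k), np.eye(k - 1, k)]).T)[0][:, 1:]
    s = c.T @ cov @ c
    p_dim = k - 1
    det = np.linalg.det(s)
    tr = np.trace(s)
    if det <= 0 or tr <= 0:
        return 0.0
    w = det / (tr / p_dim) ** p_dim
    d = n - 1
    f = 1 - (2 * p_dim**2 + p_dim + 2) / (6.0 * p_dim * d)
    chi2 = -f * d * np.log(w)
    df = p_dim * (p_dim + 1) // 2 - 1
    if df <= 0:
        return 1.0
    return float(stats.chi2.sf(chi2, df))


def rm_anova(
    data: np.ndarray, mauchly_alpha: float = 0.05
) -> RmAnovaResult:
    """One-way within-subjects ANOVA on a (subjects x levels) array.

    Applies the Greenhouse-Geisser correction to both degrees of freedom
    when Mauchly's test rejects sphericity at ``mauchly_alpha``.  A
    degenerate error term (all subjects respond identically) is reported
    with F = 0 and p = 1 by convention.
    """
    y = np.asarray(data, dtype=float)
    n, k = y.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 subjects and >= 2 levels, complete cases")
    grand = y.mean()
    ss_cond = n * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_err = np.sum((y - y.mean(axis=0) - y.mean(axis=1)[:, None] + grand) ** 2)
    df1 = k - 1.0
    df2 = (k - 1.0) * (n - 1.0)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    tot = ss_cond + ss_err
    eta = float(ss_cond / tot) if tot > 0 else 0.0
    if ms_err <= 0:
        return RmAnovaResult(0.0, df1, df2, 1.0, 1.0, 1.0, eta, False)
    F = float(ms_cond / ms_err)
    cov = np.cov(y, rowvar=False)
    mp = _mauchly_p(cov, n) if k > 2 else 1.0
    eps = 1.0
    corrected = False
    if mp < mauchly_alpha and k > 2:
        eps = _gg_epsilon(cov)
        eps = min(max(eps, 1.0 / (k - 1)), 1.0)
        corrected = True
    p = float(stats.f.sf(F, df1 * eps, df2 * eps))
    return RmAnovaResult(F, df1 * eps, df2 * eps, eps, float(mp), p, eta, corrected)


def benjamini_hochberg(
    pvals: np.ndarray, q: float = 0.05
) -> tuple[float, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Sorts the family ascending, finds the largest i with
    ``p_(i) <= (i/m) q``; that p-value is the family's critical alpha and
    every p at or below it is rejected.  Returns
    ``(critical_alpha, decisions)`` in the input order; when nothing can
    be rejected the critical alpha is 0.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    thresh = (np.arange(1, m + 1) / m) * q
    passing = np.flatnonzero(ps <= thresh)
    if passing.size == 0:
        return 0.0, np.zeros(m, dtype=bool)
    crit = float(ps[passing[-1]])
    return crit, p <= crit


def bonferroni_posthoc(
    data: np.ndarray, reference_level: int = 0
) -> dict[int, float]:
    """Bonferroni-adjusted paired t-tests of each level vs the reference.

    Raw two-sided p-values are multiplied by the number of comparisons
    and capped at 1.  Identical paired samples give adjusted p = 1.
    """
    y = np.asarray(data, dtype=float)
    n, k = y.shape
    levels = [j for j in range(k) if j != reference_level]
    out = {}
    for j in levels:
        d = y[:, j] - y[:, reference_level]
        if np.allclose(d, 0):
            out[j] = 1.0
            continue
        p = stats.ttest_rel(y[:, j], y[:, reference_level]).pvalue
        out[j] = float(min(1.0, p * len(levels)))
    return out


def build_family(
    models=("imu", "opto"),
    effects=("speed", "swing"),
    dofs=12,
    outcomes=("ROM", "meanSD", "lambda_max", "dfa_alpha", "saen"),
):
    """Enumerate the Cartesian test family over which FDR is controlled.

    ``dofs`` may be an integer count or an explicit list of labels.  The
    full configuration (2 models x 2 effects x 12 angles x 5 outcomes)
    yields 240 tests.
    """
    import pandas as pd

    if isinstance(dofs, int):
        dofs = [f"dof{i}" for i in range(dofs)]
    rows = [
        {"model": m, "effect": e, "dof": d, "outcome": o}
        for m in models
        for e in effects
        for d in dofs
        for o in outcomes
    ]
    return pd.DataFrame(rows)
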