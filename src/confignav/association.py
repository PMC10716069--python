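"""Correlations, disattenuation, correlation inference and power.

The centerpiece is the classical-test-theory correction for attenuation:
an observed correlation between two fallible measures understates the
correlation between the traits they measure, by exactly the geometric
mean of the two reliabilities under the classical model, so

    r_disattenuated = r_observed / sqrt(r_xx * r_yy)

where r_xx and r_yy are internal-consistency estimates. Sampling noise
(or a reliability estimate that is itself too low) can push the
corrected value past 1; such values are reported unclamped and flagged,
and only shrunk (to +/-0.999) inside Fisher-z machinery that requires
|r| < 1.

Inference on a single Pearson correlation uses the exact t test and the
Fisher-z confidence interval; two independent correlations are compared
with the Fisher-z test and Zou's confidence interval for r1 - r2, and
power for detecting a population correlation uses the Fisher-z normal
approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationReport",
    "CorrelationComparison",
    "pearson_r",
    "disattenuate",
    "correlation_test",
    "compare_correlations",
    "power_correlation",
    "correlation_report",
    "correlation_matrix_table",
]

#: |r| bound applied before atanh when a (possibly disattenuated) input reaches 1.
FISHER_SHRINK = 0.999


@dataclass(frozen=True)
class CorrelationReport:
    """Observed + disattenuated correlation between two measures."""

    measure_x: str
    measure_y: str
    r_observed: float
    n: int
    t: float
    df: int
    p: float
    ci95: tuple[float, float]
    r_xx: float
    r_yy: float
    r_disattenuated: float
    disattenuated_out_of_range: bool


@dataclass(frozen=True)
class CorrelationComparison:
    """Fisher-z comparison of two independent correlations."""

    label_1: str
    label_2: str
    r1: float
    n1: int
    r2: float
    n2: int
    fisher_z: float
    p: float
    zou_ci95: tuple[float, float]


def pearson_r(x, y) -> float:
    """Sample Pearson correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-D vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


def disattenuate(r_observed: float, r_xx: float, r_yy: float) -> tuple[float, bool]:
    """Correction for attenuation: r / sqrt(r_xx * r_yy).

    Returns ``(value, out_of_range)``. Values with magnitude > 1 are
    returned unclamped with the flag set (and a warning), since silent
    clamping would hide that the reliability estimates and the observed
    correlation are jointly inconsistent with the classical model.
    """
    if r_xx <= 0 or r_yy <= 0:
        raise ValueError(f"reliabilities must be positive, got ({r_xx}, {r_yy})")
    value = r_observed / np.sqrt(r_xx * r_yy)
    out_of_range = bool(abs(value) > 1.0)
    if out_of_range:
        warnings.warn(f"disattenuated correlation {value:.3f} exceeds 1 in magnitude", stacklevel=2)
    return float(value), out_of_range


def correlation_test(r: float, n: int, alpha: float = 0.05):
    """t test and Fisher-z CI for a single Pearson correlation.

    Returns ``(t, df, p, (lo, hi))`` with ``t = r * sqrt((n-2)/(1-r^2))``,
    ``df = n - 2``, a two-sided p from the t distribution, and the CI
    ``tanh(atanh(r) +/- z_{1-alpha/2} / sqrt(n-3))``.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    df = n - 2
    if abs(r) >= 1:
        t = float(np.inf) * np.sign(r)
        p = 0.0
        return t, df, p, (r, r)
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    half = zcrit / np.sqrt(n - 3)
    lo, hi = np.tanh(np.arctanh(r) - half), np.tanh(np.arctanh(r) + half)
    return float(t), df, float(p), (float(lo), float(hi))


def _shrink(r: float) -> float:
    if abs(r) >= 1.0:
        warnings.warn(f"|r| = {abs(r):.3f} >= 1 shrunk to {FISHER_SHRINK} for Fisher-z", stacklevel=3)
        return float(np.sign(r)) * FISHER_SHRINK
    return r


def compare_correlations(
    r1: float, n1: int, r2: float, n2: int, alpha: float = 0.05,
    label_1: str = "group1", label_2: str = "group2",
) -> CorrelationComparison:
    """Fisher-z test and Zou CI for the difference of two independent correlations.

    ``z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))`` with a
    two-sided normal p. Zou's 95% CI for ``r1 - r2`` combines the
    individual Fisher-z CIs:

        L = r1 - r2 - sqrt((r1 - l1)^2 + (u2 - r2)^2)
        U = r1 - r2 + sqrt((u1 - r1)^2 + (r2 - l2)^2)

    Inputs with |r| >= 1 (as disattenuated values can be) are shrunk to
    +/-0.999 with a warning before the transform.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in each group")
    r1s, r2s = _shrink(r1), _shrink(r2)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1s) - np.arctanh(r2s)) / se
    p = 2.0 * stats.norm.sf(abs(z))
    _, _, _, (l1, u1) = correlation_test(r1s, n1, alpha)
    _, _, _, (l2, u2) = correlation_test(r2s, n2, alpha)
    diff = r1s - r2s
    lo = diff - np.sqrt((r1s - l1) ** 2 + (u2 - r2s) ** 2)
    hi = diff + np.sqrt((u1 - r1s) ** 2 + (r2s - l2) ** 2)
    return CorrelationComparison(
        label_1=label_1, label_2=label_2, r1=r1, n1=n1, r2=r2, n2=n2,
        fisher_z=float(z), p=float(p), zou_ci95=(float(lo), float(hi)),
    )


def power_correlation(n: int, rho: float, alpha: float = 0.05) -> float:
    """Power of the two-sided Pearson correlation test (Fisher-z approximation).

    Under H1 the Fisher-z statistic is approximately normal with mean
    ``sqrt(n-3) * atanh(rho)`` and unit variance, so the power is
    ``Phi(mu - z_crit) + Phi(-mu - z_crit)``.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    mu = np.sqrt(n - 3) * np.arctanh(rho)
    return float(stats.norm.cdf(mu - zcrit) + stats.norm.cdf(-mu - zcrit))


def correlation_report(
    x, y, r_xx: float, r_yy: float,
    measure_x: str = "x", measure_y: str = "y", alpha: float = 0.05,
) -> CorrelationReport:
    """Full observed + disattenuated report for two score vectors."""
    r = pearson_r(x, y)
    n = len(np.asarray(x))
    t, df, p, ci = correlation_test(r, n, alpha)
    r_d, flag = disattenuate(r, r_xx, r_yy)
    return CorrelationReport(
        measure_x=measure_x, measure_y=measure_y, r_observed=r, n=n,
        t=t, df=df, p=p, ci95=ci, r_xx=r_xx, r_yy=r_yy,
        r_disattenuated=r_d, disattenuated_out_of_range=flag,
    )


def correlation_matrix_table(
    scores: pd.DataFrame, reliabilities: dict[str, float], measures: list[str] | None = None,
) -> pd.DataFrame:
    """Square measure-by-measure table: observed r below the diagonal,
    disattenuated r above, ``-`` markers (NaN) on the diagonal.
    """
    if measures is None:
        measures = [m for m in scores.columns if m in reliabilities]
    out = pd.DataFrame(np.nan, index=measures, columns=measures, dtype=float)
    for i, mi in enumerate(measures):
        for j, mj in enumerate(measures):
            if i == j:
                continue
            sub = scores[[mi, mj]].dropna()
            r = pearson_r(sub[mi], sub[mj])
            if i > j:
                out.loc[mi, mj] = r
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    out.loc[mi, mj] = disattenuate(r, reliabilities[mi], reliabilities[mj])[0]
    return out
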