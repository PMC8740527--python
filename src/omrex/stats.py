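"""Shared statistical utilities: model-II regression, exponential fits,
normality-routed two-sample comparison.

Model-I (OLS) regression lives in :mod:`omrex.rates`; this module adds the
symmetric-error standardized major axis (SMA, "model II") fit used when
both variables carry error, an exponential fit y = a·e^(bx) performed as
least squares on log-transformed y, and a two-sample comparison that
routes to a t-test or Mann–Whitney test based on Shapiro–Wilk normality of
both samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateDesignError, InsufficientDataError


@dataclass(frozen=True)
class RegressionResult:
    model: str  # "ols" | "sma" | "exponential"
    params: dict = field(default_factory=dict)
    r_squared: float = float("nan")
    p: float = float("nan")
    n: int = 0


def sma_fit(x, y) -> RegressionResult:
    """Standardized major axis (model II) linear fit.

    slope = sign(r)·sd(y)/sd(x); the line passes through the means.  The
    p-value is that of the Pearson correlation test (the standard
    significance test for an SMA slope).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise InsufficientDataError("SMA fit needs >= 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDesignError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    slope = float(np.sign(r) if r != 0 else 1.0) * float(np.std(y, ddof=1) / np.std(x, ddof=1))
    intercept = float(np.mean(y) - slope * np.mean(x))
    return RegressionResult(
        model="sma",
        params={"slope": slope, "intercept": intercept},
        r_squared=float(r**2),
        p=float(p),
        n=len(x),
    )


def exponential_fit(x, y) -> RegressionResult:
    """Fit y = a·e^(bx) by OLS on ln(y); statistics on the log scale."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise InsufficientDataError("exponential fit needs >= 3 points")
    if np.any(y <= 0):
        raise ValueError("exponential fit requires positive y")
    fit = stats.linregress(x, np.log(y))
    return RegressionResult(
        model="exponential",
        params={"a": float(np.exp(fit.intercept)), "b": float(fit.slope)},
        r_squared=float(fit.rvalue**2),
        p=float(fit.pvalue),
        n=len(x),
    )


def two_sample_compare(sample_a, sample_b, alpha: float = 0.05) -> dict:
    """Compare two samples, choosing the test from a normality check.

    Both samples are screened with Shapiro–Wilk at ``alpha``; if neither
    rejects normality a two-sample t-test is used, otherwise Mann–Whitney.
    Returns the method used, the statistic and the two-tailed p-value.
    Identical samples short-circuit to p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise InsufficientDataError("need >= 3 observations per sample")
    if np.array_equal(np.sort(a), np.sort(b)):
        return {"method": "t_test", "statistic": 0.0, "p": 1.0}
    normal = True
    for s in (a, b):
        if np.ptp(s) == 0:
            normal = False  # Shapiro undefined on constants; treat as non-normal
            break
        if stats.shapiro(s).pvalue < alpha:
            normal = False
            break
    if normal:
        t, p = stats.ttest_ind(a, b)
        return {"method": "t_test", "statistic": float(t), "p": float(p)}
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {"method": "mann_whitney", "statistic": float(u), "p": float(p)}
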