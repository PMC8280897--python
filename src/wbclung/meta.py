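"""Inverse-variance meta-analysis with a heterogeneity-driven model switch.

Per-cohort regression estimates are pooled with fixed-effect weights when
Cochran's Q shows no heterogeneity (p >= threshold) and with
DerSimonian-Laird random-effect weights otherwise.  Standard errors can be
reconstructed from printed 95% confidence intervals, so published per-cohort
rows can be re-pooled directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

#: Normal quantile used for all 95% intervals (and their inversion).
Z95 = 1.96


def se_from_ci(ci_low: float, ci_high: float) -> float:
    """Reconstruct a standard error from a 95% confidence interval.

    se = (upper - lower) / (2 * 1.96); the inverse of the ci = beta -/+
    1.96*se convention used throughout the package.
    """
    if not (np.isfinite(ci_low) and np.isfinite(ci_high)):
        raise ValueError("confidence bounds must be finite")
    if ci_high <= ci_low:
        raise ValueError(f"ci_high ({ci_high}) must exceed ci_low ({ci_low})")
    return (ci_high - ci_low) / (2.0 * Z95)


def cochran_q(betas: Sequence[float], ses: Sequence[float]) -> tuple[float, float]:
    """Cochran's Q and its chi-square p-value on k-1 degrees of freedom.

    With a single study Q is undefined; (nan, 1.0) is returned so the
    fixed-effect branch is taken downstream.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.shape != s.shape or b.ndim != 1:
        raise ValueError("betas and ses must be 1-d and of equal length")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    k = b.size
    if k == 0:
        raise ValueError("no studies supplied")
    if k == 1:
        return float("nan"), 1.0
    w = 1.0 / s**2
    pooled = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - pooled) ** 2))
    het_p = float(stats.chi2.sf(q, k - 1))
    return q, het_p


@dataclass(frozen=True)
class MetaResult:
    """Pooled estimate across cohorts for one exposure-outcome pair."""

    pooled_beta: float
    pooled_se: float
    ci_low: float
    ci_high: float
    p: float
    q_stat: float
    het_p: float
    tau2: float
    method: str  # "fixed" or "random"
    k: int


def pool(
    betas: Sequence[float],
    ses: Sequence[float],
    het_threshold: float = 0.05,
) -> MetaResult:
    """Pool per-cohort estimates, choosing fixed vs random effects by Q.

    Fixed-effect inverse-variance weights are used when the heterogeneity
    p-value is at least ``het_threshold``; otherwise DerSimonian-Laird
    tau-squared (truncated at zero) enters random-effect weights
    1/(se^2 + tau2).  A single study is passed through unchanged with
    heterogeneity p reported as 1.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    k = b.size
    if k == 0:
        raise ValueError("no studies supplied")
    q, het_p = cochran_q(b, s) if k > 1 else (float("nan"), 1.0)

    w = 1.0 / s**2
    tau2 = 0.0
    method = "fixed"
    if k > 1 and het_p < het_threshold:
        method = "random"
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / denom)
        w = 1.0 / (s**2 + tau2)

    pooled = float(np.sum(w * b) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    p = float(2.0 * stats.norm.sf(abs(pooled / pooled_se)))
    return MetaResult(
        pooled_beta=pooled,
        pooled_se=pooled_se,
        ci_low=pooled - Z95 * pooled_se,
        ci_high=pooled + Z95 * pooled_se,
        p=p,
        q_stat=q,
        het_p=het_p,
        tau2=tau2,
        method=method,
        k=int(k),
    )


def pool_from_cis(
    betas: Sequence[float],
    ci_lows: Sequence[float],
    ci_highs: Sequence[float],
    het_threshold: float = 0.05,
) -> MetaResult:
    """Pool directly from (beta, ci_low, ci_high) triples as printed in reports."""
    ses = [se_from_ci(lo, hi) for lo, hi in zip(ci_lows, ci_highs)]
    return pool(betas, ses, het_threshold=het_threshold)
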