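"""Statistical power of the test of zero correlation (point-biserial model).

The t statistic of a sample correlation r at sample size n is
t = r * sqrt(n - 2) / sqrt(1 - r^2) with n - 2 degrees of freedom.  Under a
population correlation rho, t approximately follows a noncentral t
distribution with noncentrality delta = rho * sqrt(n) / sqrt(1 - rho^2) --
the standard formulation behind "point biserial" power calculators.  A
Fisher-z normal approximation is provided as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PowerSpec",
    "power_correlation",
    "required_n",
    "min_detectable_rho",
    "bonferroni_alpha",
    "power_correlation_fisher_z",
]


@dataclass(frozen=True)
class PowerSpec:
    n: int
    rho: float
    alpha: float = 0.05
    tails: int = 2

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("n must be >= 4")
        if abs(self.rho) >= 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")


def power_correlation(spec: PowerSpec) -> float:
    """Power of the t test of H0: rho = 0 at the given settings."""
    df = spec.n - 2
    delta = abs(spec.rho) * np.sqrt(spec.n) / np.sqrt(1.0 - spec.rho**2)
    tcrit = stats.t.ppf(1.0 - spec.alpha / spec.tails, df)
    power = float(stats.nct.sf(tcrit, df, delta))
    if spec.tails == 2:
        # Opposite-tail mass; negligible for any real effect and scipy's
        # noncentral t underflows to NaN far out in that tail.
        lower = float(stats.nct.cdf(-tcrit, df, delta))
        if np.isfinite(lower):
            power += lower
    return min(max(power, 0.0), 1.0)


def power_correlation_fisher_z(spec: PowerSpec) -> float:
    """Fisher-z normal approximation of the same power (cross-check only)."""
    z = np.arctanh(abs(spec.rho))
    se = 1.0 / np.sqrt(spec.n - 3)
    zcrit = stats.norm.ppf(1.0 - spec.alpha / spec.tails)
    power = float(stats.norm.sf(zcrit - z / se))
    if spec.tails == 2:
        power += float(stats.norm.cdf(-zcrit - z / se))
    return power


def required_n(
    rho: float, alpha: float = 0.05, target_power: float = 0.8, tails: int = 2, n_max: int = 10**6
) -> int:
    """Smallest n with power >= target_power (power is monotone in n)."""
    if not alpha < target_power < 1.0:
        raise ValueError("target_power must lie in (alpha, 1)")
    lo, hi = 4, 4
    while power_correlation(PowerSpec(hi, rho, alpha, tails)) < target_power:
        lo = hi
        hi *= 2
        if hi > n_max:
            raise ValueError("target power unreachable below n_max")
    while lo < hi:
        mid = (lo + hi) // 2
        if power_correlation(PowerSpec(mid, rho, alpha, tails)) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return hi


def min_detectable_rho(
    n: int, alpha: float = 0.05, target_power: float = 0.8, tails: int = 2, tol: float = 1e-6
) -> float:
    """Effect size at which power reaches target_power, by bisection on (0, 1)."""
    if not alpha < target_power < 1.0:
        raise ValueError("target_power must lie in (alpha, 1)")
    lo, hi = 1e-12, 1.0 - 1e-12
    if power_correlation(PowerSpec(n, hi, alpha, tails)) < target_power:
        raise ValueError("target power unreachable at this n")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if power_correlation(PowerSpec(n, mid, alpha, tails)) >= target_power:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def bonferroni_alpha(alpha: float, n_comparisons: int) -> float:
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return alpha / n_comparisons
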