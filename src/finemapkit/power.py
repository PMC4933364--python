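"""Analytic power for the per-allele (log-additive) case-control test.

Normal-approximation power for the Wald test of the per-allele log-OR.  The
variance of the estimated log-OR is approximated from allele counts,
Var(beta) = 1/(2 n_cases p1 q1) + 1/(2 n_controls p0 q0), evaluated at the
case and control allele frequencies implied by the alternative.  The
minimum detectable OR inverts this by root-finding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import brentq

__all__ = ["PowerQuery", "power_trend", "min_detectable_or", "power_curve"]


@dataclass(frozen=True)
class PowerQuery:
    n_cases: int
    n_controls: int
    maf: float
    or_alt: float
    alpha: float = 0.05

    def __post_init__(self):
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.or_alt <= 0:
            raise ValueError("or_alt must be > 0")
        if min(self.n_cases, self.n_controls) < 1:
            raise ValueError("counts must be >= 1")


def _case_control_freqs(maf: float, or_alt: float) -> tuple[float, float]:
    """Allele frequencies in cases and controls under a per-allele OR.

    Controls are taken at the population frequency (rare-disease view); the
    case frequency solves p1/(1-p1) = OR * p0/(1-p0) at the allele level.
    """
    p0 = maf
    odds = or_alt * p0 / (1 - p0)
    p1 = odds / (1 + odds)
    return p1, p0


def power_trend(
    query: PowerQuery | None = None,
    *,
    n_cases: int | None = None,
    n_controls: int | None = None,
    maf: float | None = None,
    or_alt: float | None = None,
    alpha: float = 0.05,
) -> float:
    """Two-sided Wald power for the per-allele trend test."""
    q = query or PowerQuery(n_cases, n_controls, maf, or_alt, alpha)
    beta = np.log(q.or_alt)
    p1, p0 = _case_control_freqs(q.maf, q.or_alt)
    var = 1.0 / (2 * q.n_cases * p1 * (1 - p1)) + 1.0 / (2 * q.n_controls * p0 * (1 - p0))
    se = np.sqrt(var)
    z = stats.norm.ppf(1 - q.alpha / 2)
    return float(stats.norm.sf(z - beta / se) + stats.norm.sf(z + beta / se))


def min_detectable_or(
    n_cases: int,
    n_controls: int,
    maf: float,
    alpha: float = 0.05,
    power: float = 0.8,
    or_max: float = 50.0,
) -> float:
    """Smallest per-allele OR > 1 detectable at the target power.

    Bisection (Brent) on the OR until the analytic power matches the target
    within 1e-6.  Raises if the target power is not bracketed below
    ``or_max``.
    """
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")

    def gap(or_alt):
        return power_trend(PowerQuery(n_cases, n_controls, maf, or_alt, alpha)) - power

    lo = 1.0 + 1e-9
    if gap(lo) > 0:
        return lo
    if gap(or_max) < 0:
        raise ValueError(f"target power {power} not attainable below OR={or_max}")
    return float(brentq(gap, lo, or_max, xtol=1e-9, rtol=1e-10))


def power_curve(n_cases, n_controls, mafs, ors, alpha=0.05):
    """Power over a (maf, OR) grid; rows suitable for a TSV dump."""
    rows = []
    for maf in mafs:
        for or_alt in ors:
            rows.append(
                {
                    "maf": maf,
                    "odds_ratio": or_alt,
                    "power": power_trend(PowerQuery(n_cases, n_controls, maf, or_alt, alpha)),
                }
            )
    return rows
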