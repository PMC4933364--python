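"""Variant-level quality control for genotyped and imputed SNPs.

Genotyped SNPs are excluded on call rate (< 98%), departure from
Hardy-Weinberg equilibrium in controls (exact-test P < 1e-4), and low minor
allele frequency.  Imputed SNPs are filtered on imputation quality (Rsq)
with MAF-dependent cutoffs: common SNPs (MAF > 0.01) are dropped at
Rsq <= 0.3, low-frequency SNPs (MAF 0.005-0.01) at Rsq < 0.5, and rare SNPs
(MAF < 0.005) at Rsq < 0.99.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "VariantQCStats",
    "QCDecision",
    "hwe_exact_test",
    "hwe_chisq_test",
    "filter_genotyped",
    "filter_imputed",
    "qc_variant",
]


@dataclass(frozen=True)
class VariantQCStats:
    variant_id: str
    maf: float
    source: str = "genotyped"  # genotyped | imputed
    call_rate: float = 1.0
    hwe_p_controls: float = 1.0
    rsq: float | None = None

    def __post_init__(self):
        if not 0 <= self.maf <= 0.5:
            raise ValueError("maf must lie in [0, 0.5]")
        for name in ("call_rate", "hwe_p_controls"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.rsq is not None and not 0 <= self.rsq <= 1:
            raise ValueError("rsq must lie in [0, 1]")
        if self.source not in ("genotyped", "imputed"):
            raise ValueError("source must be 'genotyped' or 'imputed'")


@dataclass(frozen=True)
class QCDecision:
    keep: bool
    reasons: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.keep != (len(self.reasons) == 0):
            raise ValueError("keep must be true exactly when no rule fired")


def _decision(reasons) -> QCDecision:
    reasons = tuple(reasons)
    return QCDecision(keep=not reasons, reasons=reasons)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact conditional test of Hardy-Weinberg proportions.

    Conditional on the observed allele counts, the probability of each
    possible heterozygote count is computed by the standard recurrence and
    the P-value is the summed probability of all configurations no more
    probable than the observed one.  Monomorphic samples return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_aa + n_Aa  # minor-allele copies (relabel below if needed)
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0

    # heterozygote counts share the parity of the rare-allele count
    het_min = rare % 2
    probs = {}
    # start from the maximum heterozygote count and recurse downwards:
    # P(het-2)/P(het) = het*(het-1) / ((rare-het+2)*(2n-rare-het+2))
    het = rare if (rare % 2 == het_min) else rare - 1
    log_p = 0.0  # unnormalised, relative
    cur = het
    logs = {cur: 0.0}
    while cur - 2 >= het_min:
        ratio = (cur * (cur - 1)) / ((rare - cur + 2) * (2 * n - rare - cur + 2))
        log_p += math.log(ratio)
        cur -= 2
        logs[cur] = log_p
    m = max(logs.values())
    total = sum(math.exp(v - m) for v in logs.values())
    probs = {k: math.exp(v - m) / total for k, v in logs.items()}

    p_obs = probs.get(n_Aa)
    if p_obs is None:
        raise ValueError("heterozygote count inconsistent with allele counts")
    # small tolerance so equal-probability configurations are included
    p = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12))
    return min(1.0, p)


def hwe_chisq_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """One-df chi-square HWE test; fast alternative to the exact test."""
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one genotype required")
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = ((obs - exp) ** 2 / exp).sum()
    return float(stats.chi2.sf(chi2, df=1))


def filter_genotyped(
    stats_: VariantQCStats,
    call_rate_min: float = 0.98,
    hwe_alpha: float = 1e-4,
    maf_min: float = 0.005,
) -> QCDecision:
    """Exclusion rules for directly genotyped SNPs.

    Drops a variant when call rate < 98%, when the control-sample HWE
    P-value falls below 1e-4, or when the MAF falls below ``maf_min``
    (the published analysis does not state its MAF cutoff; 0.005 mirrors the
    lowest imputation stratum and is configurable).
    """
    if stats_.source != "genotyped":
        raise ValueError("filter_genotyped applies to genotyped variants")
    reasons = []
    if stats_.call_rate < call_rate_min:
        reasons.append("call_rate")
    if stats_.hwe_p_controls < hwe_alpha:
        reasons.append("hwe")
    if stats_.maf < maf_min:
        reasons.append("maf")
    return _decision(reasons)


def filter_imputed(maf: float, rsq: float) -> QCDecision:
    """MAF-stratified imputation-quality filter.

    Comparator directions follow the published rules exactly: MAF > 0.01
    drops Rsq <= 0.3 (non-strict); MAF in [0.005, 0.01] drops Rsq < 0.5;
    MAF < 0.005 drops Rsq < 0.99.
    """
    if not 0 <= maf <= 0.5:
        raise ValueError("maf must lie in [0, 0.5]")
    if not 0 <= rsq <= 1:
        raise ValueError("rsq must lie in [0, 1]")
    reasons = []
    if maf > 0.01:
        if rsq <= 0.3:
            reasons.append("rsq_common")
    elif maf >= 0.005:
        if rsq < 0.5:
            reasons.append("rsq_low_freq")
    else:
        if rsq < 0.99:
            reasons.append("rsq_rare")
    return _decision(reasons)


def qc_variant(stats_: VariantQCStats, **genotyped_kwargs) -> QCDecision:
    """Route a variant to the genotyped or imputed rule set."""
    if stats_.source == "genotyped":
        return filter_genotyped(stats_, **genotyped_kwargs)
    if stats_.rsq is None:
        raise ValueError("imputed variant requires an rsq value")
    return filter_imputed(stats_.maf, stats_.rsq)
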