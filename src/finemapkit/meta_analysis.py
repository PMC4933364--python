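"""Inverse-variance weighted fixed-effects meta-analysis with Cochran's Q.

Study-level (and stratum-level: cancer and adenoma case-control series are
analysed separately and enter the meta-analysis as separate units) log-OR
estimates are combined with weights w_i = 1/se_i^2.  Heterogeneity is
summarised by Cochran's Q, chi-square with k-1 df under homogeneity; no
random-effects model is fitted — Q and its P-value are reported, not acted
on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = ["MetaResult", "ivw_fixed", "cochran_q", "meta_by_variant"]


@dataclass(frozen=True)
class MetaResult:
    variant_id: str
    beta_meta: float
    se_meta: float
    p_meta: float
    q: float
    p_het: float
    k: int
    degenerate_het: bool = False  # k < 2: Q undefined, reported as 0/1

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta_meta))

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return (
            float(np.exp(self.beta_meta - z * self.se_meta)),
            float(np.exp(self.beta_meta + z * self.se_meta)),
        )


class NoDataError(ValueError):
    """All contributing units were excluded; nothing to combine."""


def _clean(estimates: Iterable) -> list[tuple[float, float]]:
    """Accept (beta, se) pairs or objects with beta/se/converged attributes."""
    out = []
    for est in estimates:
        if hasattr(est, "beta"):
            if getattr(est, "converged", True) is False:
                continue
            beta, se = float(est.beta), float(est.se)
        else:
            beta, se = float(est[0]), float(est[1])
        if not se > 0:
            raise ValueError("standard errors must be positive")
        out.append((beta, se))
    return out


def ivw_fixed(estimates: Iterable, variant_id: str = "") -> MetaResult:
    """Fixed-effects inverse-variance weighted combination.

    Non-converged units are excluded and ``k`` reflects the exclusion.  With
    a single unit the estimate passes through unchanged.
    """
    units = _clean(estimates)
    if not units:
        raise NoDataError("no converged estimates to meta-analyse")
    beta = np.array([u[0] for u in units])
    se = np.array([u[1] for u in units])
    w = 1.0 / se**2
    beta_meta = float((w * beta).sum() / w.sum())
    se_meta = float(1.0 / np.sqrt(w.sum()))
    z = beta_meta / se_meta
    p_meta = float(2 * stats.norm.sf(abs(z)))
    q, p_het, degenerate = _cochran_q_arrays(beta, w, beta_meta)
    return MetaResult(
        variant_id=variant_id,
        beta_meta=beta_meta,
        se_meta=se_meta,
        p_meta=p_meta,
        q=q,
        p_het=p_het,
        k=len(units),
        degenerate_het=degenerate,
    )


def _cochran_q_arrays(beta, w, beta_meta):
    k = len(beta)
    if k < 2:
        return 0.0, 1.0, True
    q = float((w * (beta - beta_meta) ** 2).sum())
    p_het = float(stats.chi2.sf(q, df=k - 1))
    return q, p_het, False


def cochran_q(estimates: Iterable) -> tuple[float, float]:
    """Cochran's Q and its chi-square(k-1) tail probability.

    With fewer than two units heterogeneity is undefined; (0, 1) is returned
    (the degenerate flag lives on MetaResult for the combined path).
    """
    units = _clean(estimates)
    if len(units) < 2:
        return 0.0, 1.0
    beta = np.array([u[0] for u in units])
    w = 1.0 / np.array([u[1] for u in units]) ** 2
    beta_meta = (w * beta).sum() / w.sum()
    q, p_het, _ = _cochran_q_arrays(beta, w, beta_meta)
    return q, p_het


def meta_by_variant(per_study_results: Sequence[Sequence]) -> list[MetaResult]:
    """Meta-analyse aligned per-study association scans variant by variant.

    ``per_study_results`` is a list of per-study lists of AssocResult, each
    ordered over the same variants.  Variants whose units all failed are
    skipped.
    """
    out = []
    if not per_study_results:
        return out
    n_var = len(per_study_results[0])
    for scan in per_study_results:
        if len(scan) != n_var:
            raise ValueError("per-study scans must cover the same variants")
    for j in range(n_var):
        units = [scan[j] for scan in per_study_results]
        vid = units[0].variant_id
        try:
            out.append(ivw_fixed(units, variant_id=vid))
        except NoDataError:
            continue
    return out
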