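"""Per-study case-control association testing on allele dosages.

Disease status is regressed on the expected alternate-allele count (dosage,
0-2) with covariate adjustment, by unconditional logistic regression under a
log-additive genetic model.  Inference is Wald: the per-allele odds ratio is
exp(beta) with a symmetric 95% CI on the log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AssocResult",
    "EmptyRegionScanWarning",
    "fit_logistic_dosage",
    "run_region_scan",
    "MAX_ITER",
    "SEPARATION_BETA",
]

MAX_ITER = 50
LL_TOL = 1e-8
#: |beta| beyond this is treated as (quasi-)separation, i.e. non-convergence.
SEPARATION_BETA = 15.0


class EmptyRegionScanWarning(UserWarning):
    """Region contained no testable variants after QC."""


@dataclass(frozen=True)
class AssocResult:
    variant_id: str
    study_id: str
    beta: float
    se: float
    p: float
    n_cases: int
    n_controls: int
    converged: bool = True
    note: str = ""

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return float(np.exp(self.beta - z * self.se)), float(np.exp(self.beta + z * self.se))


def _failed(variant_id, study_id, n_cases, n_controls, note) -> AssocResult:
    return AssocResult(
        variant_id=variant_id,
        study_id=study_id,
        beta=float("nan"),
        se=float("nan"),
        p=float("nan"),
        n_cases=n_cases,
        n_controls=n_controls,
        converged=False,
        note=note,
    )


def fit_logistic_dosage(
    phenotype,
    dosage,
    covariates=None,
    variant_id: str = "",
    study_id: str = "",
) -> AssocResult:
    """ML logistic fit of case status on dosage (plus covariates).

    The dosage coefficient is the per-allele log-OR; its standard error comes
    from the observed information and the P-value from the two-sided Wald
    statistic.  Constant dosage, collinearity or separation yield a result
    flagged ``converged=False`` with a diagnostic note, never a silent
    estimate.
    """
    y = np.asarray(phenotype, dtype=float)
    d = np.asarray(dosage, dtype=float)
    if y.shape[0] != d.shape[0]:
        raise ValueError("phenotype and dosage lengths differ")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("phenotype must be binary 0/1")
    if d.min() < 0 or d.max() > 2:
        raise ValueError("dosages must lie in [0, 2]")
    n_cases = int(y.sum())
    n_controls = int(y.shape[0] - n_cases)
    if n_cases == 0 or n_controls == 0:
        raise ValueError("need at least one case and one control")

    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != y.shape[0]:
            cov = cov.T
        if cov.shape[0] != y.shape[0]:
            raise ValueError("covariate rows must align with phenotype")
        X = np.column_stack([np.ones_like(d), d, cov])
    else:
        X = np.column_stack([np.ones_like(d), d])

    if np.ptp(d) == 0:
        return _failed(variant_id, study_id, n_cases, n_controls, "constant_dosage")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(
                method="newton", maxiter=MAX_ITER, tol=LL_TOL, disp=0, warn_convergence=False
            )
        except Exception as exc:  # singular matrix, perfect separation, ...
            return _failed(variant_id, study_id, n_cases, n_controls, f"fit_error:{type(exc).__name__}")

    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if not fit.mle_retvals.get("converged", False):
        return _failed(variant_id, study_id, n_cases, n_controls, "no_convergence")
    if abs(beta) > SEPARATION_BETA or not np.isfinite(se) or se <= 0:
        return _failed(variant_id, study_id, n_cases, n_controls, "separation")

    z = beta / se
    return AssocResult(
        variant_id=variant_id,
        study_id=study_id,
        beta=beta,
        se=se,
        p=float(2 * stats.norm.sf(abs(z))),
        n_cases=n_cases,
        n_controls=n_controls,
        converged=True,
    )


def run_region_scan(study, region=None, variant_ids=None, extra_covariate=None) -> list[AssocResult]:
    """One association fit per region variant present in a study dataset.

    ``study`` is a StudyDataset; variants are taken from ``region.variants``
    (or ``variant_ids``) intersected with the study's variant set.
    Non-converged variants are retained, flagged, and left to downstream
    ranking to exclude.  ``extra_covariate`` (e.g. the top-SNP dosage in a
    conditional scan) is appended to the study covariates.
    """
    wanted = list(variant_ids) if variant_ids is not None else list(region.variants)
    index = {v: i for i, v in enumerate(study.variant_ids)}
    present = [v for v in wanted if v in index]
    if not present:
        warnings.warn(
            f"region scan in study {study.study_id}: no testable variants",
            EmptyRegionScanWarning,
            stacklevel=2,
        )
        return []
    cov = study.covariates
    if extra_covariate is not None:
        extra = np.asarray(extra_covariate, dtype=float).reshape(-1, 1)
        cov = extra if cov is None else np.column_stack([cov, extra])
    results = []
    for vid in present:
        results.append(
            fit_logistic_dosage(
                study.phenotype,
                study.dosages[:, index[vid]],
                covariates=cov,
                variant_id=vid,
                study_id=study.study_id,
            )
        )
    return results
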