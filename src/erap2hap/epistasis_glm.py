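"""SNP-SNP interaction (epistasis) testing by logistic regression.

The headline test is a likelihood-ratio test of the logistic model
logit P(case) = b0 + b1*dose_a + b2*dose_b + b3*dose_a*dose_b
against the model without the product term.  Allele-dosage coding is
additive (0/1/2 copies of the minor allele) by default, matching the usual
epistasis convention; a dominant (carrier 0/1) coding is also available.
Model fitting is delegated to statsmodels' Logit (Newton/IRLS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genotype_model import CohortLabels, GenotypeTable
from .popgen_stats import TestResult

__all__ = ["GlmFit", "fit_logistic", "interaction_test"]


@dataclass
class GlmFit:
    """A fitted logistic regression."""

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    log_likelihood: float
    converged: bool
    separation: bool = False
    gradient_max: float = float("nan")


def fit_logistic(
    design: np.ndarray,
    outcome: np.ndarray,
    names: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> GlmFit:
    """Maximum-likelihood logistic fit of a binary outcome on a design matrix.

    The design must already contain an intercept column if one is wanted.
    (Quasi-)complete separation is detected and returned as a flagged,
    non-converged fit rather than raised.
    """
    design = np.asarray(design, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if design.ndim != 2 or design.shape[0] != outcome.shape[0]:
        raise ValueError("design and outcome shapes disagree")
    if design.shape[0] <= design.shape[1]:
        raise ValueError("need more observations than covariates")
    uniq = np.unique(outcome)
    if uniq.size < 2:
        raise ValueError("outcome is constant")
    if not np.isin(uniq, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    names = names or [f"x{j}" for j in range(design.shape[1])]

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    model = sm.Logit(outcome, design)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="newton", maxiter=max_iter, tol=tol, disp=False)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return GlmFit(
            {n: float("nan") for n in names},
            {n: float("nan") for n in names},
            float("nan"),
            converged=False,
            separation=True,
        )
    grad_max = float(np.abs(model.score(res.params)).max())
    separation = bool(np.abs(res.params).max() > 15) and not res.mle_retvals.get(
        "converged", False
    )
    return GlmFit(
        dict(zip(names, map(float, res.params))),
        dict(zip(names, map(float, res.bse))),
        float(res.llf),
        converged=bool(res.mle_retvals.get("converged", True)) and grad_max < 1e-4,
        separation=separation,
        gradient_max=grad_max,
    )


def _dosage_columns(
    table: GenotypeTable, snp_a: str, snp_b: str, labels: CohortLabels, coding: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    labels.validate_against(table)
    labeled = [s for s in table.samples if s in labels.status]
    if not labeled:
        raise ValueError("no labeled samples in the genotype table")
    sub = table.subset(labeled)
    da = sub.minor_dosage(snp_a)
    db = sub.minor_dosage(snp_b)
    y = np.array([1.0 if labels.status[s] == "case" else 0.0 for s in sub.samples])
    keep = ~np.isnan(da) & ~np.isnan(db)
    da, db, y = da[keep], db[keep], y[keep]
    if coding == "dominant":
        da = (da > 0).astype(float)
        db = (db > 0).astype(float)
    elif coding != "additive":
        raise ValueError(f"unknown coding {coding!r}")
    return da, db, y


def interaction_test(
    table: GenotypeTable,
    snp_a: str,
    snp_b: str,
    labels: CohortLabels,
    coding: str = "additive",
) -> TestResult:
    """Likelihood-ratio test for SNP x SNP interaction on case status.

    Compares the logistic model with main effects plus the dose_a*dose_b
    product against the main-effects model (1 df).  When the product column
    is collinear with the included columns the statistic is 0 by definition.
    """
    da, db, y = _dosage_columns(table, snp_a, snp_b, labels, coding)
    n = y.size
    ones = np.ones(n)
    reduced = np.column_stack([ones, da, db])
    full = np.column_stack([ones, da, db, da * db])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        return TestResult(0.0, 1.0, "lrt", df=1, warning="interaction collinear")
    fit_reduced = fit_logistic(reduced, y, ["intercept", "dose_a", "dose_b"])
    fit_full = fit_logistic(
        full, y, ["intercept", "dose_a", "dose_b", "dose_a:dose_b"]
    )
    if fit_full.separation or fit_reduced.separation:
        return TestResult(0.0, 1.0, "lrt", df=1, warning="separation")
    lrt = max(0.0, 2.0 * (fit_full.log_likelihood - fit_reduced.log_likelihood))
    return TestResult(lrt, float(stats.chi2.sf(lrt, 1)), "lrt", df=1)
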