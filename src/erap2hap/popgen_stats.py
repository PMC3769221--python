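"""Hardy-Weinberg testing, single-SNP case-control association, Bonferroni.

All tests return a :class:`TestResult` carrying the statistic, degrees of
freedom where applicable, the p-value and a method tag.  Allelic association
uses a two-sided Fisher exact test on the 2x2 allele-count table (probabilities
no larger than the observed table's are summed), with a Haldane-corrected odds
ratio when a cell is empty.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genotype_model import GenotypeCounts

__all__ = [
    "TestResult",
    "AssociationResult",
    "hwe_test",
    "allelic_association",
    "genotypic_association",
    "bonferroni",
    "BonferroniResult",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: int | None = None
    warning: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value out of range: {self.p_value}")


@dataclass(frozen=True)
class AssociationResult:
    test: TestResult
    odds_ratio: float
    table: tuple[tuple[int, int], tuple[int, int]]  # ((case minor, case major), (ctrl ...))


# ---------------------------------------------------------------------------
# Hardy-Weinberg


def hwe_test(counts: GenotypeCounts, method: str = "auto") -> TestResult:
    """Test genotype counts against Hardy-Weinberg proportions.

    ``chisq``: 1-df goodness of fit of (hom_major, het, hom_minor) against
    n*(p^2, 2pq, q^2).  ``exact``: conditional exact test — the p-value sums
    the probabilities of all heterozygote counts no more probable than the
    observed one, given the allele counts.  ``auto`` uses the exact test when
    the minor-allele count is below 100 and the chi-square otherwise.
    """
    n = counts.n_typed
    if n == 0:
        raise ValueError("no typed genotypes")
    n_minor = counts.minor_allele_count
    if n_minor == 0 or n_minor == 2 * n:
        warnings.warn("monomorphic SNP: HWE test degenerate, p = 1", stacklevel=2)
        return TestResult(0.0, 1.0, "hwe_degenerate", warning="monomorphic")
    if method == "auto":
        method = "exact" if min(n_minor, 2 * n - n_minor) < 100 else "chisq"
    if method == "chisq":
        q = n_minor / (2 * n)
        p = 1.0 - q
        expected = np.array([p * p, 2 * p * q, q * q]) * n
        observed = counts.as_array()
        stat = float(((observed - expected) ** 2 / expected).sum())
        return TestResult(stat, float(stats.chi2.sf(stat, 1)), "chisq", df=1)
    if method == "exact":
        return _hwe_exact(counts)
    raise ValueError(f"unknown HWE method {method!r}")


def _hwe_exact(counts: GenotypeCounts) -> TestResult:
    """Exact HWE test on the conditional distribution of heterozygote count.

    Given n genotypes and n_a copies of the rarer allele, the number of
    heterozygotes n_ab under HWE has probability
    P(n_ab) ∝ n! / (n_aa! n_ab! n_bb!) * 2^{n_ab}
    with n_aa = (n_a - n_ab)/2.  The p-value sums P over all feasible n_ab
    with P(n_ab) <= P(observed).
    """
    n = counts.n_typed
    n_a = min(counts.minor_allele_count, counts.major_allele_count)
    obs_het = counts.n_het

    def log_prob(n_ab: int) -> float:
        n_aa = (n_a - n_ab) // 2
        n_bb = n - n_aa - n_ab
        return (
            n_ab * math.log(2)
            - math.lgamma(n_aa + 1)
            - math.lgamma(n_ab + 1)
            - math.lgamma(n_bb + 1)
        )

    feasible = range(n_a % 2, n_a + 1, 2)
    logs = {h: log_prob(h) for h in feasible}
    log_norm = _logsumexp(list(logs.values()))
    p_obs = logs[obs_het] - log_norm
    p_value = sum(
        math.exp(lp - log_norm) for lp in logs.values() if lp - log_norm <= p_obs + 1e-12
    )
    # statistic reported as the observed heterozygote count
    return TestResult(float(obs_het), min(p_value, 1.0), "hwe_exact")


def _logsumexp(values: list[float]) -> float:
    m = max(values)
    return m + math.log(sum(math.exp(v - m) for v in values))


# ---------------------------------------------------------------------------
# case-control association


def allelic_association(
    case: GenotypeCounts, control: GenotypeCounts
) -> AssociationResult:
    """Two-sided Fisher exact test on the 2x2 allele-count table.

    Rows are case/control, columns minor/major allele counts.  The odds ratio
    is (case minor * control major) / (case major * control minor), with 0.5
    added to every cell when any cell is zero (Haldane-Anscombe).
    """
    if case.n_typed == 0 or control.n_typed == 0:
        raise ValueError("both case and control groups must have typed genotypes")
    a, b = case.minor_allele_count, case.major_allele_count
    c, d = control.minor_allele_count, control.major_allele_count
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return AssociationResult(
        TestResult(float(orr), float(p), "fisher_exact"),
        float(orr),
        ((a, b), (c, d)),
    )


def genotypic_association(case: GenotypeCounts, control: GenotypeCounts) -> TestResult:
    """Pearson chi-square on the 3x2 genotype-by-status table.

    Genotype rows with zero total are dropped and the degrees of freedom
    reduced accordingly.
    """
    table = np.column_stack([case.as_array(), control.as_array()])
    table = table[table.sum(axis=1) > 0]
    if table.shape[0] < 2:
        raise ValueError("degenerate genotype table: fewer than 2 non-empty rows")
    if (table.sum(axis=0) == 0).any():
        raise ValueError("one group has no typed genotypes")
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(float(stat), float(p), "chisq", df=int(df))


# ---------------------------------------------------------------------------
# multiple testing


@dataclass(frozen=True)
class BonferroniResult:
    threshold: float
    reject: tuple[bool, ...]
    p_corrected: tuple[float, ...]


def bonferroni(p_values: list[float], alpha: float = 0.05) -> BonferroniResult:
    """Bonferroni control: reject iff p <= alpha / m over m tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    if len(p_values) == 0:
        raise ValueError("empty p-value list")
    m = len(p_values)
    threshold = alpha / m
    return BonferroniResult(
        threshold,
        tuple(p <= threshold for p in p_values),
        tuple(min(1.0, p * m) for p in p_values),
    )
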