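"""Two-SNP compound-genotype analysis and ERAP2 expression prediction.

A *compound genotype* is the joint genotype of one individual at two SNPs —
here rs2248374 (the splice-site SNP whose G allele abolishes full-length
ERAP2 via nonsense-mediated decay) and rs2549782 (the N392K coding SNP).
This module builds the 3x3 observed table per cohort group, computes expected
cell counts from observed allele frequencies under two nulls, tests observed
against expected per cell, quantifies the power to detect a rare compound
homozygote, and predicts ERAP2 / 392N protein dosage from the genotype pair.

Expected-count modes
--------------------
``naive_product``
    Each cell's frequency is the plain product of its four constituent allele
    frequencies, with *no* heterozygote multiplicity factor (an AG cell uses
    f_A * f_G, not 2 f_A f_G).  This is the convention used in the published
    analysis this package reproduces (e.g. expected AA,TT frequency
    0.34 * 0.34 * 0.67 * 0.67 = 0.052); its nine cells sum to less than n.
``hwe_multinomial``
    The statistically standard null: the product of the two single-SNP
    Hardy-Weinberg genotype probabilities; cells sum to n exactly.

Both modes are always available side by side; ``naive_product`` is the
default for reproduction runs and ``hwe_multinomial`` is recommended for new
analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .genotype_model import (
    MISSING,
    CohortLabels,
    GenotypeTable,
    SNPDef,
)
from .popgen_stats import TestResult

__all__ = [
    "CompoundGenotypeTable",
    "ExpectedCounts",
    "ExpressionPrediction",
    "PHASE_DEPENDENT",
    "compound_table",
    "expected_counts",
    "observed_vs_expected_test",
    "detection_power",
    "predict_expression",
    "compatible_phases",
]

GENOTYPE_ORDER = (2, 1, 0)  # copies of the index allele, descending


@dataclass
class CompoundGenotypeTable:
    """3x3 joint genotype counts for a SNP pair.

    Rows index the genotype at ``snp_a`` and columns the genotype at
    ``snp_b``, ordered by copies of each SNP's *index allele* descending
    (2, 1, 0).  The index allele defaults to the minor allele but can be any
    of the two — for the ERAP2 pair the customary presentation indexes
    rs2248374 by its minor A allele and rs2549782 by its major T allele, so
    the top-left cell is the AA,TT compound homozygote.
    """

    snp_a: str
    snp_b: str
    index_allele_a: str
    index_allele_b: str
    counts: np.ndarray  # (3, 3) int
    group: str = "all"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 3):
            raise ValueError("compound genotype table must be 3x3")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def row_labels(self) -> list[str]:
        return [f"{self.snp_a}:{c}x{self.index_allele_a}" for c in GENOTYPE_ORDER]

    def index_allele_frequency(self, which: str) -> float:
        """Observed frequency of the index allele at SNP 'a' or 'b'."""
        dosage = np.array(GENOTYPE_ORDER, dtype=float)
        if which == "a":
            marg = self.counts.sum(axis=1)
        elif which == "b":
            marg = self.counts.sum(axis=0)
        else:
            raise ValueError("which must be 'a' or 'b'")
        return float((marg * dosage).sum() / (2 * marg.sum()))


@dataclass
class ExpectedCounts:
    """Expected 3x3 compound-genotype counts under a chosen null."""

    mode: str  # naive_product | hwe_multinomial
    freq_a: float  # frequency of the index allele at SNP a
    freq_b: float  # frequency of the index allele at SNP b
    n: int
    expected: np.ndarray  # (3, 3) float, same orientation as the observed table

    @property
    def frequencies(self) -> np.ndarray:
        return self.expected / self.n


PHASE_DEPENDENT = "phase_dependent"


@dataclass(frozen=True)
class ExpressionPrediction:
    """Predicted protein dosage from the rs2248374 x rs2549782 genotype pair.

    ``erap2_dosage`` counts functional full-length ERAP2 alleles (= copies of
    the rs2248374 A allele; the G allele is null through nonsense-mediated
    decay of its splice variant).  ``n392_dosage`` counts expressed copies of
    the 392N variant: haplotypes carrying both rs2248374 A and rs2549782 T.
    For the unphased double heterozygote this is 0 or 1 depending on phase
    and is reported as ``"phase_dependent"``.
    """

    erap2_dosage: int
    n392_dosage: int | str

    @property
    def erap2_symbol(self) -> str:
        return {0: "-", 1: "+", 2: "++"}[self.erap2_dosage]

    @property
    def n392_symbol(self) -> str:
        if self.n392_dosage == PHASE_DEPENDENT:
            return "+/-"
        return {0: "-", 1: "+", 2: "++"}[self.n392_dosage]


# ---------------------------------------------------------------------------
# observed table


def compound_table(
    table: GenotypeTable,
    snp_a: str,
    snp_b: str,
    labels: CohortLabels | None = None,
    index_allele_a: str | None = None,
    index_allele_b: str | None = None,
    subset: Iterable[str] | None = None,
) -> dict[str, CompoundGenotypeTable]:
    """Observed 3x3 compound-genotype tables, overall and per label group.

    Samples missing either SNP are excluded.  Returns a dict with key
    ``"all"`` and, when ``labels`` is given, ``"case"`` and ``"control"``
    (restricted to labeled samples present in the table).
    """
    def_a = table.snp(snp_a)
    def_b = table.snp(snp_b)
    index_allele_a = index_allele_a or def_a.minor_allele
    index_allele_b = index_allele_b or def_b.minor_allele

    def build(sample_subset: Iterable[str] | None, group: str) -> CompoundGenotypeTable:
        idx = table.sample_indices(sample_subset)
        ca = table.column(snp_a)[idx]
        cb = table.column(snp_b)[idx]
        keep = (ca != MISSING) & (cb != MISSING)
        ca, cb = ca[keep], cb[keep]
        if group == "all" and ca.size == 0:
            raise ValueError(
                f"no samples typed at both {snp_a} and {snp_b}"
            )
        counts = np.zeros((3, 3), dtype=int)
        for ga, gb in zip(ca, cb):
            ia = _orient(ga, def_a, index_allele_a)
            ib = _orient(gb, def_b, index_allele_b)
            counts[ia, ib] += 1
        return CompoundGenotypeTable(
            snp_a, snp_b, index_allele_a, index_allele_b, counts, group
        )

    out = {"all": build(subset, "all")}
    if labels is not None:
        labels.validate_against(table)
        base = set(table.samples) if subset is None else set(subset)
        for group, members in (("control", labels.controls()), ("case", labels.cases())):
            chosen = [s for s in members if s in base]
            if not chosen:
                raise ValueError(f"no labeled {group} samples in the table")
            out[group] = build(chosen, group)
    return out


def _orient(call: int, snp: SNPDef, index_allele: str) -> int:
    """Row/column index (0,1,2) for a call given the index allele."""
    if index_allele == snp.minor_allele:
        copies = call  # call codes count minor copies
    elif index_allele == snp.major_allele:
        copies = 2 - call
    else:
        raise ValueError(f"{snp.id}: {index_allele!r} is not one of its alleles")
    return GENOTYPE_ORDER.index(copies)


# ---------------------------------------------------------------------------
# expected counts


def expected_counts(
    freq_a: float, freq_b: float, n: int, mode: str = "naive_product"
) -> ExpectedCounts:
    """Expected 3x3 compound-genotype counts from two allele frequencies.

    ``freq_a``/``freq_b`` are the frequencies of the index alleles of the two
    SNPs (rows/columns ordered by index-allele copies 2, 1, 0).  See module
    docstring for the two modes.
    """
    if not (0.0 <= freq_a <= 1.0 and 0.0 <= freq_b <= 1.0):
        raise ValueError("allele frequencies must lie in [0,1]")
    if n <= 0:
        raise ValueError("n must be positive")
    if freq_a in (0.0, 1.0) or freq_b in (0.0, 1.0):
        warnings.warn(
            "degenerate allele frequency: some expected cells are 0", stacklevel=2
        )

    def geno_probs(f: float, multiplicity: bool) -> np.ndarray:
        two = 2.0 if multiplicity else 1.0
        return np.array([f * f, two * f * (1 - f), (1 - f) * (1 - f)])

    if mode == "naive_product":
        pa = geno_probs(freq_a, multiplicity=False)
        pb = geno_probs(freq_b, multiplicity=False)
    elif mode == "hwe_multinomial":
        pa = geno_probs(freq_a, multiplicity=True)
        pb = geno_probs(freq_b, multiplicity=True)
    else:
        raise ValueError(f"unknown expectation mode {mode!r}")
    return ExpectedCounts(mode, freq_a, freq_b, n, np.outer(pa, pb) * n)


def observed_vs_expected_test(
    observed: np.ndarray | int,
    expected: ExpectedCounts,
    cell: tuple[int, int] | None = None,
) -> dict[tuple[int, int], TestResult]:
    """Per-cell 1-df chi-square of each observed count against its expectation.

    Each cell is contrasted against the rest of the cohort: the binomial
    split (cell, n - cell) is scored against (expected, n - expected) as a
    1-df goodness-of-fit.  Pass a full 3x3 ``observed`` array, or a single
    count together with ``cell=(row, col)``.
    """
    n = expected.n
    results: dict[tuple[int, int], TestResult] = {}
    if cell is not None:
        cells = {cell: int(observed)}
    else:
        observed = np.asarray(observed)
        if observed.shape != (3, 3):
            raise ValueError("observed must be a 3x3 array (or pass cell=)")
        cells = {(i, j): int(observed[i, j]) for i in range(3) for j in range(3)}
    for (i, j), obs in cells.items():
        exp = float(expected.expected[i, j])
        if exp <= 0:
            raise ValueError(f"expected count is 0 in cell ({i},{j}); test undefined")
        stat = (obs - exp) ** 2 / exp + (obs - exp) ** 2 / (n - exp)
        results[(i, j)] = TestResult(
            float(stat), float(stats.chi2.sf(stat, 1)), "chisq", df=1
        )
    return results


# ---------------------------------------------------------------------------
# detection power


def detection_power(
    p_cell: float,
    n: int,
    model: str = "at_least_one",
    alpha: float = 0.05,
    p_alt: float | None = None,
) -> float:
    """Power to detect a compound-homozygote class of frequency ``p_cell``.

    ``at_least_one``: probability that >= 1 of n individuals falls in the
    class, 1 - (1 - p_cell)^n.  ``chisq_gof``: power of the 1-df cell-vs-rest
    chi-square test of H0: frequency = p_cell at level ``alpha`` when the
    true frequency is ``p_alt`` (noncentral chi-square approximation).
    """
    if not 0.0 <= p_cell <= 1.0:
        raise ValueError("p_cell must lie in [0,1]")
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0,1)")
    if model == "at_least_one":
        return 1.0 - (1.0 - p_cell) ** n
    if model == "chisq_gof":
        if p_alt is None:
            raise ValueError("chisq_gof power requires the alternative frequency p_alt")
        ncp = n * (p_alt - p_cell) ** 2 / (p_cell * (1 - p_cell))
        crit = stats.chi2.isf(alpha, 1)
        return float(stats.ncx2.sf(crit, 1, ncp))
    raise ValueError(f"unknown power model {model!r}")


# ---------------------------------------------------------------------------
# expression prediction


def _parse_genotype(genotype: str | int, snp: SNPDef, counted: str) -> int:
    """Copies of ``counted`` allele from a genotype given as letters or code."""
    if isinstance(genotype, str):
        g = genotype.strip().upper()
        if len(g) != 2:
            raise ValueError(f"genotype {genotype!r} must be two letters")
        for letter in g:
            if letter not in (snp.major_allele, snp.minor_allele):
                raise ValueError(
                    f"{snp.id}: genotype {genotype!r} uses alleles outside "
                    f"{{{snp.major_allele},{snp.minor_allele}}}"
                )
        return sum(1 for letter in g if letter == counted)
    # integer call code counts minor copies
    copies_minor = int(genotype)
    if copies_minor not in (0, 1, 2):
        raise ValueError(f"invalid call code {genotype}")
    return copies_minor if counted == snp.minor_allele else 2 - copies_minor


_RS2248374 = SNPDef("rs2248374", major_allele="G", minor_allele="A")
_RS2549782 = SNPDef("rs2549782", major_allele="T", minor_allele="G")


def predict_expression(
    genotype_a: str | int,
    genotype_b: str | int,
    phase: tuple[str, str] | None = None,
) -> ExpressionPrediction:
    """Predict ERAP2 and 392N dosage from the rs2248374/rs2549782 genotypes.

    ``genotype_a`` is the rs2248374 genotype (letters over {A,G} or a call
    code counting minor-A copies); ``genotype_b`` the rs2549782 genotype
    (letters over {T,G} or a call code counting minor-G copies).  ``phase``
    optionally gives the two haplotypes as 2-letter strings in SNP order
    (rs2248374, rs2549782), e.g. ``("AT", "GG")``; it must be consistent with
    both genotypes and resolves the double heterozygote.

    The rules: copies of full-length ERAP2 = copies of the A allele of
    rs2248374; 392N is expressed once per haplotype pairing A (expressed)
    with T (the 392N-coding allele).
    """
    n_a = _parse_genotype(genotype_a, _RS2248374, "A")
    n_t = _parse_genotype(genotype_b, _RS2549782, "T")

    if phase is not None:
        if len(phase) != 2 or any(len(h) != 2 for h in phase):
            raise ValueError("phase must be two 2-letter haplotypes")
        hap_a = sum(1 for h in phase if h[0] == "A")
        hap_t = sum(1 for h in phase if h[1] == "T")
        if hap_a != n_a or hap_t != n_t:
            raise ValueError(
                f"phase {phase} is inconsistent with genotypes "
                f"({genotype_a!r}, {genotype_b!r})"
            )
        n392 = sum(1 for h in phase if h == "AT")
        return ExpressionPrediction(n_a, n392)

    if n_a == 0 or n_t == 0:
        return ExpressionPrediction(n_a, 0)
    if n_a == 2:
        return ExpressionPrediction(2, n_t)
    if n_t == 2:
        return ExpressionPrediction(n_a, n_a)
    # double heterozygote: A may ride with T (one 392N copy) or with G (none)
    return ExpressionPrediction(1, PHASE_DEPENDENT)


def compatible_phases(genotype_a: str | int, genotype_b: str | int) -> list[tuple[str, str]]:
    """All haplotype-pair resolutions consistent with an unphased pair."""
    n_a = _parse_genotype(genotype_a, _RS2248374, "A")
    n_t = _parse_genotype(genotype_b, _RS2549782, "T")
    alleles_a = ["A"] * n_a + ["G"] * (2 - n_a)
    alleles_b = ["T"] * n_t + ["G"] * (2 - n_t)
    phases = {
        tuple(sorted((alleles_a[0] + alleles_b[0], alleles_a[1] + alleles_b[1]))),
        tuple(sorted((alleles_a[0] + alleles_b[1], alleles_a[1] + alleles_b[0]))),
    }
    return sorted(phases)
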