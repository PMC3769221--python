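"""Synthetic diploid cohorts with a prescribed haplotype structure.

The generator draws two haplotypes per individual independently from a given
frequency vector (random mating, no inbreeding), collapses them to unphased
genotype calls, and applies independent per-SNP missingness.  The true
diplotypes are retained so that downstream estimators (EM phasing, LD, block
calling) can be checked against the generating truth.  Case/control labels
are drawn from a logistic risk model on haplotype or allele-dosage counts.

Two presets encode the locus structures this package was built around:

``african_american_5snp``
    Two complementary 5-SNP haplotypes, GTAGC at 0.436 and TAGAT at 0.564
    (SNP order rs2549782, rs2548538, rs2248374, rs2287988, rs1056893): every
    SNP pair is in complete LD (D' = 1, r^2 = 1).

``chilean_4snp_plus_partial``
    A 4-SNP block (rs2548538..rs1056893) with haplotypes TAGC at 0.339 and
    AGAT at 0.661, while rs2549782 is only partially linked: its alleles are
    mixed onto both block haplotypes.  Defaults place the T(rs2549782)+TAGC
    recombinant at 0.120, which reproduces the published pairwise structure
    (rs2248374-rs2549782 D' ~ 0.49, r^2 ~ 0.23).  The recombinant frequency
    is a free parameter because the true phased frequencies cannot be
    measured from unphased genotypes.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .genotype_model import (
    ERAP2_SNPS,
    MISSING,
    CohortLabels,
    GenotypeTable,
    SNPDef,
)

__all__ = [
    "CaseModel",
    "SimConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "attach_case_status",
    "preset",
    "cohort_from_compound_counts",
]

# Default case fraction mirrors the study design: 528 case / 575 control dyads.
DEFAULT_CASE_FRACTION = 528 / (528 + 575)


@dataclass(frozen=True)
class CaseModel:
    """Logistic risk model for case status.

    logit P(case) = intercept + sum_s dosage_log_or[s] * minor_dosage(s)
                  + sum_(a,b) interaction_log_or[(a,b)] * dose_a * dose_b
                  + sum_h haplotype_log_or[h] * copies(h)
    """

    intercept: float = math.log(DEFAULT_CASE_FRACTION / (1 - DEFAULT_CASE_FRACTION))
    dosage_log_or: dict[str, float] = field(default_factory=dict)
    interaction_log_or: dict[tuple[str, str], float] = field(default_factory=dict)
    haplotype_log_or: dict[str, float] = field(default_factory=dict)


@dataclass
class SimConfig:
    """Full specification of a simulated cohort."""

    snp_defs: tuple[SNPDef, ...]
    haplotypes: tuple[str, ...]  # allele-letter strings over snp_defs
    haplotype_freqs: tuple[float, ...]
    n_samples: int = 1100
    missing_rate: float = 0.003  # per SNP per sample, independent
    case_model: CaseModel = field(default_factory=CaseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.haplotypes) != len(self.haplotype_freqs):
            raise ValueError("haplotypes and frequencies differ in length")
        total = float(sum(self.haplotype_freqs))
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")
        if any(f < 0 for f in self.haplotype_freqs):
            raise ValueError("negative haplotype frequency")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0,1)")
        k = len(self.snp_defs)
        for hap in self.haplotypes:
            if len(hap) != k:
                raise ValueError(f"haplotype {hap!r} does not span {k} SNPs")
            for letter, snp in zip(hap, self.snp_defs):
                if letter not in (snp.major_allele, snp.minor_allele):
                    raise ValueError(f"{snp.id}: allele {letter!r} not defined")

    def minor_matrix(self) -> np.ndarray:
        """(n_haplotypes, k) 0/1 matrix of minor-allele indicators."""
        return np.array(
            [
                [int(letter == snp.minor_allele) for letter, snp in zip(hap, self.snp_defs)]
                for hap in self.haplotypes
            ],
            dtype=np.int8,
        )


@dataclass
class SimulatedCohort:
    """A simulated genotype table plus the generating truth."""

    table: GenotypeTable
    diplotypes: np.ndarray  # (n_samples, 2) indices into config.haplotypes
    config: SimConfig

    def haplotype_copies(self, haplotype: str) -> np.ndarray:
        """Per-sample copy number of a haplotype string."""
        try:
            h = self.config.haplotypes.index(haplotype)
        except ValueError:
            raise KeyError(f"haplotype {haplotype!r} not in the simulation") from None
        return (self.diplotypes == h).sum(axis=1)

    def true_minor_dosage(self, snp_id: str) -> np.ndarray:
        """Minor-allele dosage from the true diplotypes (no missingness)."""
        j = [s.id for s in self.config.snp_defs].index(snp_id)
        minor = self.config.minor_matrix()[:, j]
        return minor[self.diplotypes].sum(axis=1)


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Draw a cohort of unphased genotypes from the configured haplotype pool.

    Identical configs (including seed) produce bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    freqs = np.asarray(config.haplotype_freqs, dtype=float)
    if freqs.sum() <= 0:
        raise ValueError("degenerate frequency vector")
    freqs = freqs / freqs.sum()
    n = config.n_samples
    diplotypes = rng.choice(len(freqs), size=(n, 2), p=freqs)
    minor = config.minor_matrix()
    calls = (minor[diplotypes[:, 0]] + minor[diplotypes[:, 1]]).astype(np.int8)
    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls[mask] = MISSING
    samples = [f"S{i + 1:05d}" for i in range(n)]
    table = GenotypeTable(samples, list(config.snp_defs), calls)
    return SimulatedCohort(table, diplotypes, config)


def attach_case_status(
    cohort: SimulatedCohort,
    case_model: CaseModel | None = None,
    seed: int | None = None,
    stratum: str = "fetal",
) -> CohortLabels:
    """Draw case/control labels from the logistic risk model.

    Effects are evaluated on the *true* diplotypes (dosages unaffected by
    missingness).  ``seed`` defaults to ``config.seed + 1`` so that genotype
    and label draws are decoupled but jointly reproducible.
    """
    model = case_model if case_model is not None else cohort.config.case_model
    rng = np.random.default_rng(cohort.config.seed + 1 if seed is None else seed)
    n = cohort.table.n_samples
    logits = np.full(n, model.intercept, dtype=float)
    snp_ids = [s.id for s in cohort.config.snp_defs]
    for snp_id, beta in model.dosage_log_or.items():
        if snp_id not in snp_ids:
            raise ValueError(f"case model references unknown SNP {snp_id!r}")
        logits += beta * cohort.true_minor_dosage(snp_id)
    for (a, b), beta in model.interaction_log_or.items():
        logits += beta * cohort.true_minor_dosage(a) * cohort.true_minor_dosage(b)
    for hap, beta in model.haplotype_log_or.items():
        if hap not in cohort.config.haplotypes:
            raise ValueError(f"case model references unknown haplotype {hap!r}")
        logits += beta * cohort.haplotype_copies(hap)
    p_case = 1.0 / (1.0 + np.exp(-logits))
    is_case = rng.random(n) < p_case
    status = {
        s: ("case" if c else "control") for s, c in zip(cohort.table.samples, is_case)
    }
    return CohortLabels(status, {s: stratum for s in cohort.table.samples})


# ---------------------------------------------------------------------------
# presets


def preset(
    name: str,
    n_samples: int = 1100,
    missing_rate: float = 0.003,
    seed: int = 0,
    block_minor_freq: float = 0.339,
    partial_minor_freq: float = 0.330,
    recombinant_at_freq: float = 0.120,
) -> SimConfig:
    """Named cohort configurations for the two locus structures.

    For ``chilean_4snp_plus_partial`` the three frequency parameters are:
    ``block_minor_freq`` — frequency of the all-minor 4-SNP block haplotype
    TAGC (carries rs2248374 A); ``partial_minor_freq`` — minor G frequency of
    the partially linked rs2549782; ``recombinant_at_freq`` — frequency of
    the recombinant haplotype pairing rs2549782 T with the TAGC block (the
    combination absent from previously described populations).  Setting it to
    0 makes the AA,TT compound homozygote structurally impossible.
    """
    if name == "african_american_5snp":
        return SimConfig(
            snp_defs=ERAP2_SNPS,
            haplotypes=("GTAGC", "TAGAT"),
            haplotype_freqs=(0.436, 0.564),
            n_samples=n_samples,
            missing_rate=missing_rate,
            seed=seed,
        )
    if name == "chilean_4snp_plus_partial":
        b = block_minor_freq
        g = partial_minor_freq
        at = recombinant_at_freq
        freqs = {
            "TTAGC": at,           # T(782) on the TAGC block  (recombinant)
            "GTAGC": b - at,       # G(782) on the TAGC block
            "TAGAT": (1 - g) - at, # T(782) on the AGAT block
            "GAGAT": g - (b - at), # G(782) on the AGAT block  (recombinant)
        }
        bad = {h: f for h, f in freqs.items() if f < -1e-12}
        if bad:
            raise ValueError(f"infeasible preset frequencies: {bad}")
        haps = tuple(freqs)
        return SimConfig(
            snp_defs=ERAP2_SNPS,
            haplotypes=haps,
            haplotype_freqs=tuple(max(0.0, freqs[h]) for h in haps),
            n_samples=n_samples,
            missing_rate=missing_rate,
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}")


# ---------------------------------------------------------------------------
# fixture reconstruction from published tables


def cohort_from_compound_counts(
    counts: np.ndarray,
    snp_a: SNPDef,
    snp_b: SNPDef,
    index_allele_a: str,
    index_allele_b: str,
    n_samples: int | None = None,
    sample_prefix: str = "S",
) -> GenotypeTable:
    """Rebuild a two-SNP genotype table from a published 3x3 count table.

    ``counts[i, j]`` holds the number of samples with ``(2, 1, 0)[i]`` copies
    of ``index_allele_a`` and ``(2, 1, 0)[j]`` copies of ``index_allele_b``.
    If ``n_samples`` exceeds the table total the remainder is emitted as
    samples missing both SNPs, matching cohorts with partial typing.
    """
    counts = np.asarray(counts, dtype=int)
    rows = []
    order = (2, 1, 0)
    for i in range(3):
        for j in range(3):
            copies_a = order[i]
            copies_b = order[j]
            call_a = copies_a if index_allele_a == snp_a.minor_allele else 2 - copies_a
            call_b = copies_b if index_allele_b == snp_b.minor_allele else 2 - copies_b
            rows.extend([(call_a, call_b)] * int(counts[i, j]))
    n_typed = len(rows)
    n_total = n_samples if n_samples is not None else n_typed
    if n_total < n_typed:
        raise ValueError("n_samples smaller than the table total")
    rows.extend([(MISSING, MISSING)] * (n_total - n_typed))
    calls = np.array(rows, dtype=np.int8)
    samples = [f"{sample_prefix}{i + 1:05d}" for i in range(n_total)]
    return GenotypeTable(samples, [snp_a, snp_b], calls)
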