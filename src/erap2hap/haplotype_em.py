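"""EM estimation of haplotype frequencies from unphased genotypes, and LD.

Genotyping yields unphased calls, so multi-locus haplotype frequencies must be
estimated.  This module implements the classic expectation--maximization
estimator on the multinomial likelihood of unphased multi-locus genotypes
(Excoffier--Slatkin style): the E-step distributes each ambiguous diplotype
over its compatible haplotype pairs in proportion to the current frequency
products, the M-step re-estimates frequencies from the expected haplotype
counts, and the log-likelihood is non-decreasing at every iteration.

Haplotypes over K SNPs are represented internally as K-bit masks where bit j
set means the *minor* allele at the j-th SNP of the requested order.  Pairwise
LD statistics (D, D', r^2) are derived from the 2-locus EM distribution with
minor-allele indicator coding at both SNPs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genotype_model import (
    HET,
    HOM_MAJOR,
    HOM_MINOR,
    MISSING,
    GenotypeTable,
    SNPDef,
)

__all__ = [
    "HaplotypeDistribution",
    "LDStats",
    "LDMatrix",
    "em_haplotype_freqs",
    "em_from_pattern_counts",
    "em_from_joint_counts",
    "two_locus_counts",
    "pairwise_ld",
    "ld_matrix",
]

_REPORT_FLOOR = 1e-6  # estimated frequencies below this are reported as 0


@dataclass
class HaplotypeDistribution:
    """Population haplotype frequencies for K ordered SNPs, from EM."""

    snps: list[SNPDef]
    freq_vector: np.ndarray  # length 2^K over bitmask haplotypes (raw EM output)
    log_likelihood: float
    n_iterations: int
    converged: bool
    n_samples: int  # complete-case samples used
    loglik_path: list[float] = field(default_factory=list, repr=False)

    @property
    def snp_order(self) -> list[str]:
        return [s.id for s in self.snps]

    @property
    def k(self) -> int:
        return len(self.snps)

    def haplotype_string(self, mask: int) -> str:
        return "".join(
            s.minor_allele if (mask >> j) & 1 else s.major_allele
            for j, s in enumerate(self.snps)
        )

    @property
    def freqs(self) -> dict[str, float]:
        """Haplotype-string -> frequency, with tiny frequencies zeroed.

        Frequencies below 1e-6 are presentational noise from the EM and are
        dropped; the remainder is renormalized.
        """
        keep = {
            mask: f
            for mask, f in enumerate(self.freq_vector)
            if f >= _REPORT_FLOOR
        }
        total = sum(keep.values())
        return {
            self.haplotype_string(mask): float(f / total)
            for mask, f in sorted(keep.items(), key=lambda kv: -kv[1])
        }

    def frequency_of(self, haplotype: str) -> float:
        """Frequency of a haplotype given as an allele-letter string."""
        if len(haplotype) != self.k:
            raise ValueError(f"haplotype {haplotype!r} does not span {self.k} SNPs")
        mask = 0
        for j, (letter, snp) in enumerate(zip(haplotype, self.snps)):
            if letter == snp.minor_allele:
                mask |= 1 << j
            elif letter != snp.major_allele:
                raise ValueError(f"{snp.id}: allele {letter!r} unknown")
        return float(self.freq_vector[mask])

    def minor_frequency(self, j: int) -> float:
        """Marginal minor-allele frequency of the j-th SNP."""
        idx = np.arange(len(self.freq_vector))
        return float(self.freq_vector[(idx >> j) & 1 == 1].sum())

    def restrict(self, j_a: int, j_b: int) -> "HaplotypeDistribution":
        """Marginal 2-SNP distribution over SNP positions j_a < j_b."""
        vec = np.zeros(4)
        idx = np.arange(len(self.freq_vector))
        for mask in range(4):
            sel = (((idx >> j_a) & 1) == (mask & 1)) & (
                ((idx >> j_b) & 1) == ((mask >> 1) & 1)
            )
            vec[mask] = self.freq_vector[sel].sum()
        return HaplotypeDistribution(
            [self.snps[j_a], self.snps[j_b]],
            vec,
            self.log_likelihood,
            self.n_iterations,
            self.converged,
            self.n_samples,
        )


@dataclass(frozen=True)
class LDStats:
    """Pairwise linkage disequilibrium between two SNPs (minor-allele coding).

    ``D = p_ab - p_a * p_b`` with p_ab the coupling (minor-minor) haplotype
    frequency; ``D_prime = |D| / D_max`` with the usual frequency-constrained
    maximum; ``r_squared = D^2 / (p_a q_a p_b q_b)``.
    """

    snp_a: str
    snp_b: str
    D: float
    D_prime: float
    r_squared: float
    p_a: float
    p_b: float
    n_used: int
    defined: bool = True

    def as_dict(self) -> dict:
        return {
            "snp_a": self.snp_a,
            "snp_b": self.snp_b,
            "D": self.D,
            "D_prime": self.D_prime,
            "r2": self.r_squared,
            "p_a": self.p_a,
            "p_b": self.p_b,
            "n_used": self.n_used,
        }


# ---------------------------------------------------------------------------
# diplotype expansion


def _compatible_pairs(pattern: tuple[int, ...]) -> list[tuple[int, int]]:
    """All unordered haplotype pairs compatible with an unphased genotype.

    ``pattern`` holds per-SNP minor-allele dosage (0/1/2).  A genotype with h
    heterozygous sites expands to 2^(h-1) unordered pairs (1 pair when h = 0);
    the first heterozygous site's minor allele is pinned to the second
    haplotype to enumerate each unordered pair exactly once.
    """
    het_sites = [j for j, g in enumerate(pattern) if g == 1]
    base = 0
    for j, g in enumerate(pattern):
        if g == 2:
            base |= 1 << j
    if not het_sites:
        return [(base, base)]
    first, rest = het_sites[0], het_sites[1:]
    pairs = []
    for bits in range(1 << len(rest)):
        h1 = base
        h2 = base | (1 << first)
        for k, j in enumerate(rest):
            if (bits >> k) & 1:
                h1 |= 1 << j
            else:
                h2 |= 1 << j
        pairs.append((h1, h2))
    return pairs


# ---------------------------------------------------------------------------
# EM core (operates on aggregated genotype-pattern counts)


def em_from_pattern_counts(
    patterns: Sequence[tuple[int, ...]],
    counts: Sequence[float],
    k: int,
    tol: float = 1e-9,
    max_iter: int = 1000,
    restarts: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, float, int, bool, list[float]]:
    """Run the EM over distinct multi-locus genotype patterns.

    Returns (frequency vector over 2^k bitmask haplotypes, log-likelihood,
    iterations of the best run, converged flag, log-likelihood path).
    """
    if k < 1 or k > 10:
        raise ValueError("EM supports 1..10 SNPs")
    n_hap = 1 << k
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise ValueError("no samples with complete calls at the requested SNPs")

    expansions = [_compatible_pairs(p) for p in patterns]
    compat = sorted({h for pairs in expansions for pair in pairs for h in pair})
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, int, bool, list[float]] | None = None
    for restart in range(max(1, restarts)):
        if restart == 0:
            # deterministic start: split each pattern's mass equally over pairs
            f = np.zeros(n_hap)
            for pairs, c in zip(expansions, counts):
                w = c / len(pairs)
                for h1, h2 in pairs:
                    f[h1] += w
                    f[h2] += w
            f /= f.sum()
        else:
            f = np.zeros(n_hap)
            f[compat] = rng.dirichlet(np.ones(len(compat)))

        ll_prev = -np.inf
        path: list[float] = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            new = np.zeros(n_hap)
            ll = 0.0
            for pairs, c in zip(expansions, counts):
                if len(pairs) == 1 and pairs[0][0] == pairs[0][1]:
                    h = pairs[0][0]
                    prob = f[h] * f[h]
                    if prob <= 0:
                        prob = 1e-300
                    new[h] += 2 * c
                    ll += c * math.log(prob)
                    continue
                probs = np.array([2.0 * f[h1] * f[h2] for h1, h2 in pairs])
                total = probs.sum()
                if total <= 0:
                    probs[:] = 1.0 / len(probs)
                    total_ll = 1e-300
                else:
                    probs /= total
                    total_ll = total
                for (h1, h2), w in zip(pairs, probs):
                    new[h1] += c * w
                    new[h2] += c * w
                ll += c * math.log(total_ll)
            f = new / (2 * n)
            path.append(ll)
            if ll - ll_prev < tol and it > 1:
                converged = True
                ll_prev = ll
                break
            ll_prev = ll
        if best is None or ll_prev > best[0] + 1e-12:
            best = (ll_prev, f, it, converged, path)

    assert best is not None
    ll_best, f_best, iters, converged, path = best
    return f_best, float(ll_best), iters, converged, path


def _complete_case_patterns(
    table: GenotypeTable, snp_ids: Sequence[str]
) -> tuple[list[tuple[int, ...]], np.ndarray, int]:
    cols = np.column_stack([table.column(s) for s in snp_ids])
    complete = ~(cols == MISSING).any(axis=1)
    cols = cols[complete]
    if cols.shape[0] == 0:
        raise ValueError("no samples with complete calls at the requested SNPs")
    uniq, counts = np.unique(cols, axis=0, return_counts=True)
    patterns = [tuple(int(g) for g in row) for row in uniq]
    return patterns, counts.astype(float), int(cols.shape[0])


def em_haplotype_freqs(
    table: GenotypeTable,
    snps: Sequence[str],
    tol: float = 1e-9,
    max_iter: int = 1000,
    restarts: int = 5,
    seed: int = 0,
) -> HaplotypeDistribution:
    """Estimate haplotype frequencies for 2..10 ordered SNPs by EM.

    Samples missing any of the requested SNPs are dropped (complete-case).
    The best of ``restarts`` initializations is returned; the first start
    splits each ambiguous genotype's mass equally over its compatible pairs,
    the others are random Dirichlet draws.
    """
    if not 2 <= len(snps) <= 10:
        raise ValueError("between 2 and 10 SNPs required")
    patterns, counts, n_used = _complete_case_patterns(table, snps)
    f, ll, iters, converged, path = em_from_pattern_counts(
        patterns, counts, len(snps), tol=tol, max_iter=max_iter,
        restarts=restarts, seed=seed,
    )
    return HaplotypeDistribution(
        [table.snp(s) for s in snps], f, ll, iters, converged, n_used, path
    )


def two_locus_counts(
    table: GenotypeTable,
    snp_a: str,
    snp_b: str,
    subset: Iterable[str] | None = None,
) -> np.ndarray:
    """3x3 joint genotype counts indexed [dosage_a, dosage_b] (minor copies
    ascending 0,1,2), complete cases only."""
    idx = table.sample_indices(subset)
    ca = table.column(snp_a)[idx]
    cb = table.column(snp_b)[idx]
    keep = (ca != MISSING) & (cb != MISSING)
    ca, cb = ca[keep], cb[keep]
    out = np.zeros((3, 3), dtype=int)
    for ga, gb in zip(ca, cb):
        out[ga, gb] += 1
    return out


def em_from_joint_counts(
    counts: np.ndarray,
    snp_a: SNPDef,
    snp_b: SNPDef,
    tol: float = 1e-9,
    max_iter: int = 1000,
    restarts: int = 5,
    seed: int = 0,
) -> HaplotypeDistribution:
    """2-locus EM from a 3x3 joint genotype count table.

    ``counts[i, j]`` is the number of samples with i copies of snp_a's minor
    allele and j copies of snp_b's minor allele.  This is the entry point for
    published compound-genotype tables, where only the 9 cell counts are
    available rather than individual genotypes.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (3, 3):
        raise ValueError("expected a 3x3 joint genotype table")
    patterns = [(i, j) for i in range(3) for j in range(3)]
    flat = [counts[i, j] for i, j in patterns]
    f, ll, iters, converged, path = em_from_pattern_counts(
        patterns, flat, 2, tol=tol, max_iter=max_iter, restarts=restarts, seed=seed
    )
    return HaplotypeDistribution(
        [snp_a, snp_b], f, ll, iters, converged, int(counts.sum()), path
    )


# ---------------------------------------------------------------------------
# LD statistics


def pairwise_ld(dist: HaplotypeDistribution) -> LDStats:
    """D, D' and r^2 from a 2-SNP haplotype distribution.

    Monomorphic SNPs leave LD undefined; the result is returned flagged
    (``defined=False``) with NaN statistics.
    """
    if dist.k != 2:
        raise ValueError("pairwise_ld requires a 2-SNP distribution")
    p_a = dist.minor_frequency(0)
    p_b = dist.minor_frequency(1)
    name_a, name_b = dist.snp_order
    n = dist.n_samples
    if min(p_a, 1 - p_a, p_b, 1 - p_b) <= 0:
        return LDStats(name_a, name_b, math.nan, math.nan, math.nan,
                       p_a, p_b, n, defined=False)
    p_ab = float(dist.freq_vector[0b11])  # minor at both
    d = p_ab - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LDStats(name_a, name_b, d, min(d_prime, 1.0), min(r2, 1.0), p_a, p_b, n)


@dataclass
class LDMatrix:
    """All-pairs LD statistics for an ordered SNP list."""

    snp_ids: list[str]
    stats: dict[tuple[int, int], LDStats]  # keyed (i, j) with i < j
    pair_counts: dict[tuple[int, int], np.ndarray]  # 3x3 joint genotype counts

    def get(self, i: int, j: int) -> LDStats:
        return self.stats[(min(i, j), max(i, j))]

    def dprime_matrix(self) -> np.ndarray:
        k = len(self.snp_ids)
        m = np.full((k, k), np.nan)
        for (i, j), s in self.stats.items():
            m[i, j] = m[j, i] = s.D_prime
        return m

    def r2_matrix(self) -> np.ndarray:
        k = len(self.snp_ids)
        m = np.full((k, k), np.nan)
        for (i, j), s in self.stats.items():
            m[i, j] = m[j, i] = s.r_squared
        return m

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("snp_i\tsnp_j\tD\tD_prime\tr2\tn_used\n")
            for (i, j), s in sorted(self.stats.items()):
                fh.write(
                    f"{s.snp_a}\t{s.snp_b}\t{s.D:.6f}\t{s.D_prime:.4f}\t"
                    f"{s.r_squared:.4f}\t{s.n_used}\n"
                )

    def render_triangle(self, value: str = "r2") -> str:
        """Plain-text lower triangle of D' or r^2 (two decimals)."""
        mat = self.r2_matrix() if value == "r2" else self.dprime_matrix()
        width = max(len(s) for s in self.snp_ids)
        lines = []
        for i, name in enumerate(self.snp_ids):
            cells = [
                "  . " if math.isnan(mat[i, j]) else f"{mat[i, j]:.2f}"
                for j in range(i)
            ]
            lines.append(f"{name:>{width}} " + " ".join(cells))
        return "\n".join(lines)


def ld_matrix(
    table: GenotypeTable,
    snps: Sequence[str] | None = None,
    tol: float = 1e-9,
    max_iter: int = 1000,
    restarts: int = 5,
    seed: int = 0,
) -> LDMatrix:
    """Pairwise 2-locus EM LD over every SNP pair (complete cases per pair)."""
    snp_ids = list(snps) if snps is not None else table.snp_ids
    stats: dict[tuple[int, int], LDStats] = {}
    pair_counts: dict[tuple[int, int], np.ndarray] = {}
    for i, j in itertools.combinations(range(len(snp_ids)), 2):
        counts = two_locus_counts(table, snp_ids[i], snp_ids[j])
        pair_counts[(i, j)] = counts
        if counts.sum() == 0:
            stats[(i, j)] = LDStats(
                snp_ids[i], snp_ids[j], math.nan, math.nan, math.nan,
                math.nan, math.nan, 0, defined=False,
            )
            continue
        dist = em_from_joint_counts(
            counts, table.snp(snp_ids[i]), table.snp(snp_ids[j]),
            tol=tol, max_iter=max_iter, restarts=restarts, seed=seed,
        )
        stats[(i, j)] = pairwise_ld(dist)
    return LDMatrix(snp_ids, stats, pair_counts)
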