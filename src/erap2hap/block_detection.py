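"""Haplotype-block calling from pairwise LD under three classic rules.

The three methods mirror the standard block definitions used by LD-browsing
tools:

* ``confidence_interval`` — Gabriel-style: pairs are classified as "strong
  LD" or "evidence of recombination" from a likelihood-based confidence
  interval on |D'|, and a block is a run whose bounding pair is in strong LD
  and in which at least a given fraction of informative pairs are strong.
* ``four_gamete`` — a recombination break is declared between adjacent SNPs
  whenever all four 2-locus gametes are present above a frequency floor;
  unbroken runs form blocks.
* ``solid_spine`` — a run is a block when its first and last SNP are in
  strong LD (D' above a floor) with every intermediate SNP; weak interior
  pairs are reported as diagnostics rather than breaking the block.

SNP "position" is the input order of the SNP list; no physical coordinates
are used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotype_model import GenotypeTable
from .haplotype_em import LDMatrix, em_from_pattern_counts, ld_matrix

__all__ = [
    "BlockSet",
    "dprime_confidence_interval",
    "blocks_confidence_interval",
    "blocks_four_gamete",
    "blocks_solid_spine",
    "solid_spine_blocks_from_matrix",
]


@dataclass
class BlockSet:
    method: str
    snp_ids: list[str]
    blocks: list[tuple[int, int]]  # inclusive (first, last) SNP indices
    parameters: dict
    diagnostics: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        last_end = -1
        for first, last in self.blocks:
            if not (0 <= first < last < len(self.snp_ids)):
                raise ValueError(f"block ({first},{last}) out of range")
            if first <= last_end:
                raise ValueError("blocks overlap")
            last_end = last

    def block_members(self) -> list[list[str]]:
        return [self.snp_ids[first : last + 1] for first, last in self.blocks]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("method\tblock_index\tfirst_snp\tlast_snp\tn_snps\tdiagnostics\n")
            diag = "; ".join(self.diagnostics) or "."
            for b, (first, last) in enumerate(self.blocks):
                fh.write(
                    f"{self.method}\t{b}\t{self.snp_ids[first]}\t"
                    f"{self.snp_ids[last]}\t{last - first + 1}\t{diag}\n"
                )


def _check_ordered(table: GenotypeTable, snp_ids: list[str]) -> None:
    idx = [table.snp_index(s) for s in snp_ids]
    if idx != sorted(idx):
        raise ValueError("SNPs must be ordered by position (table column order)")


def _select_non_overlapping(
    candidates: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Greedy longest-first (ties leftmost) selection of disjoint spans."""
    chosen: list[tuple[int, int]] = []
    for first, last in sorted(candidates, key=lambda s: (-(s[1] - s[0]), s[0])):
        if all(last < f or first > l for f, l in chosen):
            chosen.append((first, last))
    return sorted(chosen)


# ---------------------------------------------------------------------------
# confidence-interval (Gabriel-style) method


def dprime_confidence_interval(
    counts: np.ndarray, n_grid: int = 201, lower_q: float = 0.05,
    upper_q: float = 0.95,
) -> tuple[float, float]:
    """Likelihood-based confidence interval on |D'| for one SNP pair.

    The 3x3 joint genotype counts (minor-allele dosage ascending) are scored
    under the 2-locus random-mating likelihood with allele frequencies fixed
    at their observed values; the one free parameter is the coupling
    haplotype frequency.  The normalized likelihood over a grid of that
    parameter is treated as a weight function on |D'| and the (5%, 95%)
    weighted quantiles are returned.

    Returns (nan, nan) for a monomorphic pair.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        return (math.nan, math.nan)
    dos_a = counts.sum(axis=1) @ np.array([0, 1, 2])
    dos_b = counts.sum(axis=0) @ np.array([0, 1, 2])
    p_a = dos_a / (2 * n)
    p_b = dos_b / (2 * n)
    if min(p_a, 1 - p_a, p_b, 1 - p_b) <= 0:
        return (math.nan, math.nan)

    lo = max(0.0, p_a + p_b - 1.0)
    hi = min(p_a, p_b)
    grid = np.linspace(lo, hi, n_grid)
    logliks = np.empty(n_grid)
    dprimes = np.empty(n_grid)
    for g, p11 in enumerate(grid):
        h11 = p11
        h10 = p_a - p11
        h01 = p_b - p11
        h00 = 1.0 - p_a - p_b + p11
        cell = np.array(
            [
                [h00 * h00, 2 * h00 * h01, h01 * h01],
                [2 * h00 * h10, 2 * h11 * h00 + 2 * h10 * h01, 2 * h01 * h11],
                [h10 * h10, 2 * h10 * h11, h11 * h11],
            ]
        )
        logliks[g] = float((counts * np.log(np.maximum(cell, 1e-300))).sum())
        d = p11 - p_a * p_b
        if d >= 0:
            d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
        else:
            d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
        dprimes[g] = abs(d) / d_max if d_max > 0 else 0.0

    w = np.exp(logliks - logliks.max())
    w /= w.sum()
    order = np.argsort(dprimes)
    cdf = np.cumsum(w[order])
    sorted_dp = dprimes[order]
    low = float(sorted_dp[np.searchsorted(cdf, lower_q)])
    high = float(sorted_dp[min(np.searchsorted(cdf, upper_q), n_grid - 1)])
    return (low, high)


def blocks_confidence_interval(
    table: GenotypeTable,
    snps: Sequence[str] | None = None,
    ci_low: float = 0.70,
    ci_high: float = 0.98,
    recomb_high: float = 0.90,
    informative_fraction: float = 0.95,
    seed: int = 0,
) -> BlockSet:
    """Gabriel-style blocks from D' confidence intervals.

    A pair is "strong LD" when its CI lower bound is >= ``ci_low`` and upper
    bound >= ``ci_high``; it shows "evidence of recombination" when the upper
    bound is < ``recomb_high``.  Spans whose bounding pair is strong and in
    which >= ``informative_fraction`` of informative pairs are strong become
    candidate blocks; disjoint spans are chosen longest-first.
    """
    snp_ids = list(snps) if snps is not None else table.snp_ids
    _check_ordered(table, snp_ids)
    mat = ld_matrix(table, snp_ids, seed=seed)
    k = len(snp_ids)
    strong = np.zeros((k, k), dtype=bool)
    informative = np.zeros((k, k), dtype=bool)
    for (i, j), counts in mat.pair_counts.items():
        low, high = dprime_confidence_interval(counts)
        if math.isnan(low):
            continue
        is_strong = low >= ci_low and high >= ci_high
        is_recomb = high < recomb_high
        strong[i, j] = strong[j, i] = is_strong
        informative[i, j] = informative[j, i] = is_strong or is_recomb

    candidates = []
    for first in range(k):
        for last in range(first + 1, k):
            if not strong[first, last]:
                continue
            n_inf = n_strong = 0
            for a in range(first, last + 1):
                for b in range(a + 1, last + 1):
                    if informative[a, b]:
                        n_inf += 1
                        n_strong += strong[a, b]
            if n_inf > 0 and n_strong / n_inf >= informative_fraction:
                candidates.append((first, last))
    return BlockSet(
        "confidence_interval",
        snp_ids,
        _select_non_overlapping(candidates),
        {
            "ci_low": ci_low,
            "ci_high": ci_high,
            "recomb_high": recomb_high,
            "informative_fraction": informative_fraction,
        },
    )


# ---------------------------------------------------------------------------
# four-gamete rule


def blocks_four_gamete(
    table: GenotypeTable,
    snps: Sequence[str] | None = None,
    fourth_gamete_min: float = 0.01,
    seed: int = 0,
) -> BlockSet:
    """Four-gamete blocks: break adjacent pairs showing all four gametes.

    For each adjacent SNP pair the 2-locus EM haplotype frequencies are
    estimated; a recombination break is declared when all four gametes have
    frequency >= ``fourth_gamete_min``.  Maximal unbroken runs of >= 2 SNPs
    are blocks.
    """
    snp_ids = list(snps) if snps is not None else table.snp_ids
    _check_ordered(table, snp_ids)
    mat = ld_matrix(table, snp_ids, seed=seed)
    k = len(snp_ids)
    breaks = []
    for i in range(k - 1):
        counts = mat.pair_counts[(i, i + 1)]
        patterns = [(a, b) for a in range(3) for b in range(3)]
        flat = [counts[a, b] for a, b in patterns]
        if sum(flat) == 0:
            breaks.append(True)
            continue
        f, *_ = em_from_pattern_counts(patterns, flat, 2, seed=seed)
        breaks.append(bool((f >= fourth_gamete_min).sum() == 4))

    blocks = []
    start = 0
    for i in range(k - 1):
        if breaks[i]:
            if i > start:
                blocks.append((start, i))
            start = i + 1
    if k - 1 > start:
        blocks.append((start, k - 1))
    return BlockSet(
        "four_gamete", snp_ids, blocks, {"fourth_gamete_min": fourth_gamete_min}
    )


# ---------------------------------------------------------------------------
# solid spine of LD


def solid_spine_blocks_from_matrix(
    dprime: np.ndarray, dprime_min: float = 0.80
) -> tuple[list[tuple[int, int]], list[tuple[tuple[int, int], tuple[int, int]]]]:
    """Solid-spine block spans from a symmetric D' matrix.

    A span [i, j] qualifies when the first and last SNP each have
    D' >= ``dprime_min`` with every intermediate SNP (for an adjacent pair,
    the pair itself must pass).  Returns the chosen spans together with the
    weak interior pairs of each span (pairs below the floor that the spine
    rule does not check) as (span, pair) tuples — diagnostics, not breaks.
    """
    k = dprime.shape[0]

    def qualifies(first: int, last: int) -> bool:
        if last == first + 1:
            return bool(dprime[first, last] >= dprime_min)
        return all(
            dprime[first, m] >= dprime_min and dprime[m, last] >= dprime_min
            for m in range(first + 1, last)
        )

    candidates = [
        (i, j) for i in range(k) for j in range(i + 1, k) if qualifies(i, j)
    ]
    blocks = _select_non_overlapping(candidates)
    weak_pairs = []
    for first, last in blocks:
        for a in range(first, last + 1):
            for b in range(a + 1, last + 1):
                if dprime[a, b] < dprime_min:
                    weak_pairs.append(((first, last), (a, b)))
    return blocks, weak_pairs


def blocks_solid_spine(
    table: GenotypeTable,
    snps: Sequence[str] | None = None,
    dprime_min: float = 0.80,
    seed: int = 0,
) -> BlockSet:
    """Solid-spine-of-LD blocks from the pairwise D' matrix."""
    snp_ids = list(snps) if snps is not None else table.snp_ids
    _check_ordered(table, snp_ids)
    mat = ld_matrix(table, snp_ids, seed=seed)
    dp = mat.dprime_matrix()
    dp = np.nan_to_num(dp, nan=0.0)
    blocks, weak_pairs = solid_spine_blocks_from_matrix(dp, dprime_min)
    diagnostics = [
        f"block {snp_ids[span[0]]}..{snp_ids[span[1]]}: interior pair "
        f"({snp_ids[a]},{snp_ids[b]}) D'={dp[a, b]:.2f} < {dprime_min:.2f}"
        for span, (a, b) in weak_pairs
    ]
    return BlockSet(
        "solid_spine", snp_ids, blocks, {"dprime_min": dprime_min}, diagnostics
    )
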