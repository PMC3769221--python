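"""Published summary data for the ERAP2 locus used as analysis inputs.

These constants transcribe the printed cohort summaries of the Chilean and
African-American ERAP2 preeclampsia case--control study: per-SNP minor-allele
counts, and the Chilean fetal 3x3 compound-genotype table for the
rs2248374 x rs2549782 pair.  They let every downstream statistic be recomputed
from the published counts without access to individual-level genotypes.

Compound-genotype tables are indexed rows x cols = rs2248374 genotype
(AA, AG, GG — copies of the minor A allele descending) x rs2549782 genotype
(TT, GT, GG — copies of the major T allele descending).
"""

from __future__ import annotations

import numpy as np

from .genotype_model import GenotypeCounts

__all__ = [
    "CHILEAN_FETAL_COMPOUND_TOTAL",
    "CHILEAN_FETAL_COMPOUND_CONTROL",
    "CHILEAN_FETAL_COMPOUND_CASE",
    "COMPOUND_ROW_LABELS",
    "COMPOUND_COL_LABELS",
    "chilean_fetal_rs2248374_counts",
    "chilean_fetal_rs2549782_counts",
    "CHILEAN_FETAL_ALLELE_COUNTS",
    "CHILEAN_FETAL_N",
    "CHILEAN_MATERNAL_N",
]

COMPOUND_ROW_LABELS = ("AA", "AG", "GG")  # rs2248374, minor A copies 2/1/0
COMPOUND_COL_LABELS = ("TT", "GT", "GG")  # rs2549782, major T copies 2/1/0

# Chilean fetal (neonatal) compound genotypes, all samples (n typed = 1097).
CHILEAN_FETAL_COMPOUND_TOTAL = np.array(
    [
        [0, 90, 43],
        [151, 248, 81],
        [346, 138, 0],
    ]
)

# Same table split by pregnancy outcome (normal-term controls / PE cases).
CHILEAN_FETAL_COMPOUND_CONTROL = np.array(
    [
        [0, 41, 28],
        [93, 126, 41],
        [176, 69, 0],
    ]
)
CHILEAN_FETAL_COMPOUND_CASE = np.array(
    [
        [0, 49, 15],
        [58, 122, 40],
        [170, 69, 0],
    ]
)

# Cohort sizes: 528 case dyads and 575 control dyads per stratum; the full
# genotyped set per stratum is reported as 1100 samples.
CHILEAN_FETAL_N = 1100
CHILEAN_MATERNAL_N = 1100

# Chilean fetal minor-allele counts (minor allele, count in controls/cases,
# group sizes 575 controls / 528 cases).
CHILEAN_FETAL_ALLELE_COUNTS = {
    "rs2549782": {"minor": "G", "control": 374, "case": 351},
    "rs2548538": {"minor": "T", "control": 393, "case": 340},
    "rs2248374": {"minor": "A", "control": 400, "case": 348},
    "rs2287988": {"minor": "G", "control": 393, "case": 339},
    "rs1056893": {"minor": "C", "control": 389, "case": 335},
}
CHILEAN_FETAL_GROUP_SIZES = {"control": 575, "case": 528}


def chilean_fetal_rs2248374_counts() -> GenotypeCounts:
    """rs2248374 genotype marginals of the Chilean fetal compound table.

    Minor allele is A; rows AA/AG/GG of the compound table map to
    hom_minor/het/hom_major.  Three of the 1100 samples are untyped for
    the pair.
    """
    t = CHILEAN_FETAL_COMPOUND_TOTAL
    return GenotypeCounts(
        n_hom_major=int(t[2].sum()),
        n_het=int(t[1].sum()),
        n_hom_minor=int(t[0].sum()),
        n_missing=CHILEAN_FETAL_N - int(t.sum()),
    )


def chilean_fetal_rs2549782_counts() -> GenotypeCounts:
    """rs2549782 genotype marginals; minor allele is G (columns GG/GT/TT)."""
    t = CHILEAN_FETAL_COMPOUND_TOTAL
    return GenotypeCounts(
        n_hom_major=int(t[:, 0].sum()),
        n_het=int(t[:, 1].sum()),
        n_hom_minor=int(t[:, 2].sum()),
        n_missing=CHILEAN_FETAL_N - int(t.sum()),
    )
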