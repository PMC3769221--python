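import numpy as np
import pytest

from erap2hap.datasets import CHILEAN_FETAL_COMPOUND_TOTAL
from erap2hap.genotype_model import ERAP2_SNPS, GenotypeTable, SNPDef
from erap2hap.synthetic_cohort import cohort_from_compound_counts

SNP374 = next(s for s in ERAP2_SNPS if s.id == "rs2248374")
SNP782 = next(s for s in ERAP2_SNPS if s.id == "rs2549782")


@pytest.fixture(scope="session")
def snp374() -> SNPDef:
    return SNP374


@pytest.fixture(scope="session")
def snp782() -> SNPDef:
    return SNP782


@pytest.fixture(scope="session")
def chilean_pair_counts_minor() -> np.ndarray:
    """Chilean fetal rs2248374 x rs2549782 joint counts, minor-dosage ascending.

    Rows: copies of A (rs2248374 minor) 0,1,2; columns: copies of G
    (rs2549782 minor) 0,1,2.  Derived from the published table, whose rows
    are AA/AG/GG (A descending) and columns TT/GT/GG (G ascending).
    """
    return CHILEAN_FETAL_COMPOUND_TOTAL[::-1, :].copy()


@pytest.fixture(scope="session")
def chilean_fetal_table() -> GenotypeTable:
    """Two-SNP genotype table reconstructed from the published fetal counts.

    1097 typed samples plus 3 untyped, matching the reported cohort of 1100.
    """
    return cohort_from_compound_counts(
        CHILEAN_FETAL_COMPOUND_TOTAL,
        SNP374,
        SNP782,
        index_allele_a="A",
        index_allele_b="T",
        n_samples=1100,
    )


@pytest.fixture()
def perfect_two_snp_table() -> GenotypeTable:
    """60 samples at 2 SNPs drawn from a two-haplotype system (r^2 = 1)."""
    snps = [SNPDef("s1", "A", "G"), SNPDef("s2", "T", "C")]
    calls = np.array([[0, 0]] * 20 + [[1, 1]] * 28 + [[2, 2]] * 12, dtype=np.int8)
    return GenotypeTable([f"P{i}" for i in range(60)], snps, calls)
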