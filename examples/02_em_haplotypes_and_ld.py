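"""EM haplotype frequencies and LD for the published Chilean fetal pair.

Phase cannot be measured by genotyping, so the four two-locus haplotype
frequencies of rs2248374 (alleles A/G) x rs2549782 (T/G) are estimated by EM
from the published 3x3 compound-genotype counts.  D' ~ 0.49 and r^2 ~ 0.23
quantify the *partial* linkage that distinguishes the Chilean structure from
the complete LD seen in previously described populations.
"""

from erap2hap import em_from_joint_counts, pairwise_ld
from erap2hap.datasets import CHILEAN_FETAL_COMPOUND_TOTAL
from erap2hap.genotype_model import ERAP2_SNPS

snp374 = next(s for s in ERAP2_SNPS if s.id == "rs2248374")
snp782 = next(s for s in ERAP2_SNPS if s.id == "rs2549782")

# reorient the published table (rows AA/AG/GG, cols TT/GT/GG) to
# minor-allele dosage ascending for both SNPs
counts = CHILEAN_FETAL_COMPOUND_TOTAL[::-1, :]
dist = em_from_joint_counts(counts, snp374, snp782, seed=0)

print(f"EM converged in {dist.n_iterations} iterations "
      f"(log-likelihood {dist.log_likelihood:.1f}, n = {dist.n_samples})")
print("haplotype (rs2248374, rs2549782) frequencies:")
for hap, freq in dist.freqs.items():
    print(f"  {hap[0]}-{hap[1]}: {freq:.3f}")

ld = pairwise_ld(dist)
print(f"\nD = {ld.D:+.3f}, D' = {ld.D_prime:.2f}, r2 = {ld.r_squared:.2f}")
print("-> the A-T haplotype (~0.12) lets 392N be expressed, something the")
print("   complete-LD structure of other populations makes impossible")
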