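"""Expected two-SNP compound-genotype counts from observed allele frequencies.

The Chilean fetal cohort has rs2248374 A at 0.34 and rs2549782 T at 0.67.
Under the naive product null the AA,TT compound homozygote is expected at
frequency 0.34^2 * 0.67^2 ~ 0.052, i.e. ~57 of 1100 samples — yet zero were
observed.  The HWE-multinomial column shows the standard null (heterozygote
cells carry a factor 2) for comparison.
"""

from erap2hap import expected_counts, observed_vs_expected_test

naive = expected_counts(0.34, 0.67, 1100, "naive_product")
hwe = expected_counts(0.34, 0.67, 1100, "hwe_multinomial")

print("cell (copies A, copies T) | naive expected | HWE expected")
labels = (2, 1, 0)
for i, ca in enumerate(labels):
    for j, cb in enumerate(labels):
        print(f"  ({ca}, {cb})                  | {naive.expected[i, j]:6.1f}"
              f"         | {hwe.expected[i, j]:6.1f}")
print(f"naive total {naive.expected.sum():.1f} (< n by design), "
      f"HWE total {hwe.expected.sum():.1f}")

test = observed_vs_expected_test(0, naive, cell=(0, 0))[(0, 0)]
print(f"\nobserved 0 AA,TT vs expected {naive.expected[0, 0]:.1f}: "
      f"chi2 = {test.statistic:.1f}, p = {test.p_value:.2e}")
print("-> the absence of the AA,TT class is wildly incompatible with chance")
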