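"""Haplotype-block calling on the two simulated locus structures.

The two-haplotype preset puts all five SNPs in one block under every rule;
the partially-linked preset leaves rs2549782 outside the four-SNP block,
reproducing the contrast between the two population structures.
"""

from erap2hap import (
    blocks_confidence_interval,
    blocks_four_gamete,
    blocks_solid_spine,
    ld_matrix,
    preset,
    simulate_cohort,
)

for name in ("african_american_5snp", "chilean_4snp_plus_partial"):
    table = simulate_cohort(preset(name, seed=7)).table
    print(f"\npreset {name} (n = {table.n_samples})")
    print(ld_matrix(table, seed=7).render_triangle("dprime"))
    for fn in (blocks_confidence_interval, blocks_four_gamete, blocks_solid_spine):
        bs = fn(table, seed=7)
        members = [",".join(b) for b in bs.block_members()] or ["(none)"]
        print(f"  {bs.method:21s} -> {'; '.join(members)}")
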