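"""Predicted ERAP2 / 392N protein dosage for every compound genotype.

The rs2248374 G allele is functionally null (nonsense-mediated decay of its
splice variant), so full-length ERAP2 dosage equals the number of A alleles.
392N (encoded by rs2549782 T) is only expressed from haplotypes that pair T
with an expressed A — which for the unphased double heterozygote depends on
phase.
"""

from erap2hap import predict_expression
from erap2hap.compound_genotype import compatible_phases

print("rs2248374  rs2549782  ERAP2  392N")
for g374 in ("AA", "AG", "GG"):
    for g782 in ("TT", "GT", "GG"):
        pred = predict_expression(g374, g782)
        print(f"   {g374}        {g782}      {pred.erap2_symbol:3s}   "
              f"{pred.n392_symbol}")

print("\nresolving the double heterozygote by phase:")
for phase in compatible_phases("AG", "GT"):
    pred = predict_expression("AG", "GT", phase=phase)
    print(f"  haplotypes {phase[0]}/{phase[1]} -> 392N dosage {pred.n392_dosage}")
print("-> A-with-T expresses one 392N copy; A-with-G expresses none")
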