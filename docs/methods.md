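# Methods

This note documents the statistical models implemented in `erap2hap`, the
choices made where the methodology was genuinely open, and what the synthetic
cohorts do and do not establish about real data.

## Data model

Genotypes are unphased biallelic calls — hom-major / het / hom-minor /
missing — stored as an n×K int8 matrix with a fixed major/minor assignment
per SNP (`SNPDef`).  Phase is never read from input: genotyping assays cannot
measure it, so all haplotype-level quantities are population-level estimates.
Missing calls are removed per SNP (or per SNP pair / per K-SNP set for
multi-locus statistics): pairwise deletion, chosen because published
per-pair totals (1097 typed of 1100 samples) show exactly this convention.
VCF input maps REF→major and ALT→minor and rejects multi-allelic records;
the CSV dialect (`sample,<snp>,...` with two-letter cells, `--` missing) is
order-insensitive within a cell.

## EM haplotype-frequency estimation

For K ordered SNPs (2 ≤ K ≤ 10) the frequencies of the 2^K haplotypes are
estimated by expectation–maximization on the multinomial likelihood of
unphased multi-locus genotypes (the classic gene-counting / Excoffier–
Slatkin formulation).  A genotype with h heterozygous sites is compatible
with 2^(h−1) unordered haplotype pairs; the E-step distributes each
genotype's mass over its pairs in proportion to 2·f_a·f_b at the current
frequencies, the M-step re-normalizes expected haplotype counts.  The
log-likelihood is non-decreasing per iteration (asserted in tests).

Numerical choices: convergence at Δlog-likelihood < 1e-9, max 1000
iterations (non-convergence is flagged on the result, not raised), 5
restarts of which the first splits each ambiguous genotype's mass equally
over its pairs and the rest are seeded Dirichlet draws; the best likelihood
wins.  Estimated frequencies below 1e-6 are reported as 0 and the rest
renormalized (presentational only; the raw vector is preserved on the
object).  Because the EM preserves allele-frequency margins exactly, the
2-locus problem has a single free parameter (the coupling haplotype
frequency); tests verify the EM against a 1e-4 grid search of that
parameter and, for the published fetal table, against the closed fixed-point
equation for the double-heterozygote coupling mass (m ≈ 25 of 248).

## LD statistics

With minor-allele indicator coding at both SNPs, D = p_AB − p_A·p_B,
D' = |D|/D_max with D_max = min(p_A(1−p_B), (1−p_A)p_B) for D > 0 and
min(p_A p_B, (1−p_A)(1−p_B)) for D < 0, and r² = D²/(p_A q_A p_B q_B).
Monomorphic SNPs leave LD undefined; such pairs are returned flagged rather
than raised, and block callers treat them as uninformative.

## Block detection

Three standard rules operate on the pairwise 2-locus EM estimates; SNP
"position" is input order (no physical coordinates — appropriate for a
single-gene SNP panel).

* **Confidence interval (Gabriel-style).**  For each pair, the likelihood of
  the 9-cell genotype table is profiled over the coupling frequency (margins
  fixed at observed allele frequencies); normalized likelihood weights on
  |D'| give 5%/95% bounds.  A pair is *strong LD* if lower ≥ 0.70 and upper
  ≥ 0.98, *recombinant* if upper < 0.90.  A span qualifies when its bounding
  pair is strong and ≥ 95% of its informative pairs are strong; disjoint
  spans are chosen longest-first.  The thresholds are the published defaults
  of the standard LD-browsing tool; the likelihood-weighted CI construction
  was an open choice and is documented here as this package's.
* **Four-gamete rule.**  A break is declared between adjacent SNPs whenever
  all four 2-locus gametes have EM frequency ≥ 0.01; unbroken runs of ≥ 2
  SNPs are blocks.
* **Solid spine.**  A span qualifies when its first and last SNP each have
  D' ≥ 0.80 with every intermediate SNP (an adjacent pair must itself pass).
  Interior pairs below the floor — including the endpoint pair of longer
  spans, which the spine rule does not constrain — are reported as per-block
  diagnostics rather than breaks.

## Single-SNP tests

Hardy–Weinberg: 1-df χ² goodness of fit against n(p², 2pq, q²), or the
conditional exact test summing probabilities of heterozygote counts no more
probable than observed; the default uses the exact test when the rarer
allele has < 100 copies.  Allelic association: two-sided Fisher exact test
on the 2×2 allele-count table (summing tables with probability ≤ observed;
sidedness was unstated in the source analysis and two-sided is the field
convention), odds ratio with Haldane–Anscombe 0.5 correction when a cell is
empty.  Genotypic association: Pearson χ² on the 3×2 table with empty
genotype rows dropped and df reduced.  Bonferroni: reject iff p ≤ α/m.

## Compound-genotype analysis

The 3×3 observed table indexes each SNP by a chosen *index allele*
(descending copy number), so the canonical ERAP2 presentation — rs2248374 by
minor A, rs2549782 by major T, AA,TT top-left — falls out naturally.

Two expectation modes are always computed side by side:

* `naive_product`: cell frequency = product of the four constituent allele
  frequencies with **no heterozygote multiplicity factor** (AA,TG expects
  f_A²·f_T·f_G, not 2f_T f_G).  This is the convention of the analysis this
  package reproduces — its published expected counts (57/28/14/111/215 at
  0.34/0.67, n=1100) are only recovered without the factor 2 — and is
  therefore the default in fidelity runs.  Its cells sum to < n whenever
  either SNP is polymorphic.
* `hwe_multinomial`: product of the two single-SNP HWE genotype
  probabilities; cells sum to n.  Recommended for new analyses.

In fidelity runs allele frequencies are rounded to 2 decimals before
expectation (matching published precision); full precision otherwise.

The observed-vs-expected test contrasts one cell against the rest:
χ² = (O−E)²/E + (O−E)²/(n−E), 1 df.  The source analysis did not state its
contrast; this cell-vs-rest construction reproduces the published p-values
to order of magnitude (e.g. observed 0 vs expected 57.1 at n=1100 gives
χ² = 60.2, p ≈ 8.5e-15) but not digit-for-digit, so tests assert magnitudes
only.

Detection power for a rare cell-class: `at_least_one` = 1−(1−p)^n (the
probability the cohort contains any carrier) or `chisq_gof`, the noncentral-χ²
power of the 1-df cell-vs-rest test under a stated alternative frequency.
The model behind the originally reported 65% figure was unstated, so the
power API exposes both models rather than asserting a number.

## Expression prediction

Full-length ERAP2 dosage = copies of rs2248374 A (the G splice variant is
degraded).  392N dosage = number of haplotypes pairing A with rs2549782 T;
it is fully determined by the unphased pair except for the AG,GT double
heterozygote, which is reported as `phase_dependent` unless an explicit
haplotype pair is supplied (validated against the genotypes).  Prediction is
the rule table only — no quantitative mRNA/NMD modeling.

## Epistasis

logit P(case) = β₀ + β₁·dose_a + β₂·dose_b + β₃·dose_a·dose_b, additive
(0/1/2) dosage coding by default (dominant carrier coding available),
fitted by statsmodels' Newton/IRLS Logit.  The headline p-value is the
1-df likelihood-ratio test of β₃ — preferred over the Wald test for
stability at small cell counts.  Perfect separation is detected and
returned flagged; a product column collinear with the main effects yields
LRT = 0 by definition.  No covariates beyond the two SNPs are modeled.

## Synthetic cohorts

`simulate_cohort` draws two haplotypes per individual independently from the
configured frequency vector (random mating, no inbreeding, no mutation or
recombination process — frequencies are taken as given), collapses to
unphased calls, and applies independent per-SNP missingness (default 0.003,
the rate implied by 1097 typed of 1100).  True diplotypes are retained for
oracle checks.  Case labels are Bernoulli draws from the logistic risk model
above evaluated on true dosages; the default is intercept-only at case
fraction 528/1103, the study's design ratio.

Preset parameters are the published population quantities: the two-haplotype
system at 0.436/0.564, and the 4-SNP block at 0.339/0.661 with rs2549782 G
at 0.330.  The block preset's one free quantity — the frequency of the
recombinant haplotype pairing rs2549782 T with the minor block — defaults to
0.120, the value the 2-locus EM assigns to the A–T haplotype in the
published fetal table; it is exposed as a parameter because phased
frequencies are not measurable from unphased data (setting it to 0 makes the
AA,TT compound homozygote structurally impossible).

What the simulations do **not** emulate: genotyping error, missingness that
is correlated across SNPs or with genotype, population stratification,
relatedness (the real cohorts contain maternal–fetal dyads), and any
environmental or polygenic contribution to case status.  Passing recovery
and calibration tests on these cohorts therefore shows the estimators are
correct under their own assumptions, not that those assumptions hold in any
particular real cohort.

## Problem sizes and calibration checks

The packaged checks use n = 1100 cohorts: 100 seeds per preset for block-
structure recovery and 400 null replicates for type-I error of the allelic
Fisher test and the interaction LRT (band 0.03–0.07 at α = 0.05; with 400
replicates the Monte Carlo SE of a 0.05 rate is ≈ 0.011, and a long-run
check at 1600 replicates puts the LRT at 0.054).  The full suite runs in
well under a minute on one core.

## Known limitations

* EM is exact-in-the-limit but can in principle find local maxima for K > 2;
  restarts mitigate, and for the 2-locus case the grid-search cross-check
  rules it out on tested tables.
* The Gabriel CI construction here (profile-likelihood weights at fixed
  margins) is one of several reasonable variants; block membership is robust
  to the variant on the structures tested, exact CI bounds are not.
* Published association p-values from the original cohorts (0.46, 0.78,
  0.842) cannot be recomputed exactly from the printed summary tables
  because per-SNP missingness in each group is unknown; tests assert
  non-significance rather than values.
* The printed frequency column of one published compound-genotype row is
  internally inconsistent with its count (43/1097 ≈ 0.04, printed 0.09);
  counts are treated as authoritative throughout.
* Cohort sizes are reported both as 1100 per stratum and as 528+575 = 1103
  dyads; fidelity computations use n = 1100.
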