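# haplocc

Multi-stage candidate-gene association analysis for case-control studies of
tag SNPs grouped into gene regions — the analysis stack used in
candidate-pathway epidemiology (e.g. one-carbon-metabolism genes and renal
cell carcinoma): single-SNP logistic models, gene-level minimum-p
permutation tests, EM haplotype reconstruction with posterior-dosage GLMs,
sliding-window haplotype screening, and diet-stratified interaction
analysis. A synthetic cohort generator reproduces the structure such
studies assume, so every stage is testable end to end without access to
subject-level data.

## Who this is for

Genetic epidemiologists analysing unphased biallelic genotypes from a
case-control design: disease status, covariates (age, sex, study centre,
lifestyle factors) and 0/1/2 minor-allele counts for tag SNPs assigned
5'→3' to named gene regions. Input formats are PLINK text ped/map plus a
delimited subject table.

## The models

**Single-SNP.** Unconditional logistic regression adjusted for age
(continuous), sex and centre; codominant coding (heterozygote and
rare-homozygote indicators vs. the common homozygote) and additive trend
coding (0/1/2 rare-allele count). Odds ratios with Wald 95% CIs,
`exp(β ± 1.96·SE)`; trend p is the two-sided Wald test on the dosage term.
Benjamini–Hochberg step-up FDR within gene.

**Gene-level min-P.** The statistic is the minimum per-SNP additive-model
p-value in a gene; its null distribution comes from shuffling case/control
labels within centre strata (preserving frequency-matched margins) while
genotypes and covariates stay attached to subjects:
`p_emp = (#{permutation min-p ≤ observed} + 1) / (B + 1)`, with BH FDR
across genes.

**Haplotypes.** Frequencies over a SNP window are estimated by the EM
algorithm for unphased genotypes under random mating: E-step posteriors
over compatible phase pairs ∝ `f(h₁)·f(h₂)·(2 if h₁≠h₂)`, M-step
frequencies = expected haplotype counts / 2n. Association uses
posterior-expected per-subject copy numbers (dosages ∈ [0,2]) of each
non-reference haplotype in the logistic model; the most frequent haplotype
is the reference and haplotypes under 5% are pooled as "rare". The global
test is the joint Wald chi-square on all haplotype coefficients. Pairwise
LD r² among controls comes from the two-locus EM frequencies:
`r² = D²/(p_A q_A p_B q_B)`, `D = f(AB) − f(A)f(B)`.

**Haplowalk and stratification.** Consecutive 3-SNP windows are scanned
along each gene; windows with FDR-adjusted global p < 0.1 mark regions of
interest. Analyst-chosen blocks are then analysed with the same GLM, and
re-fit within control-based tertiles of vegetable/alcohol intake with the
haplotype dictionary frozen from the full-sample EM; haplotype × stratum
interactions and genotype × country heterogeneity are tested by likelihood
ratio.

## Worked example

Simulate a study-scale cohort (777 cases / 1,035 controls) carrying a
4-SNP risk haplotype at ~6.4% control frequency with a per-copy OR of
1.37, then run the block analysis:

```python
import haplocc as h

cfg = h.single_gene_config(seed=5)
gm, subjects, truth = h.simulate_cohort(cfg)
res = h.block_analysis(gm, subjects,
                       ["rs12483553", "rs2838950", "rs2838951", "rs17004785"])
print(res.table[["haplotype", "freq", "OR", "lcl", "ucl", "p"]].round(3))
print(f"global Wald p = {res.global_p:.3f}")
```

```
haplotype  freq    OR   lcl   ucl     p
  G-C-G-G 0.436 1.000   NaN   NaN   NaN
  G-C-C-G 0.224 0.905 0.754 1.087 0.287
  G-T-C-G 0.237 0.864 0.722 1.035 0.112
  A-C-C-C 0.062 1.445 1.075 1.943 0.015
     rare 0.040 0.847 0.584 1.229 0.383
global Wald p = 0.018
```

The reference row (most frequent haplotype, OR fixed at 1.00) anchors the
table; the planted A-C-C-C haplotype is recovered at OR 1.45 (95% CI
1.08–1.94) — its CI covers the true value 1.37 — while the unplanted
haplotypes sit near the null.

The same cohort can be written to files and pushed through every stage
from the shell:

```bash
haplocc simulate --seed 5 --out run/
haplocc run-all -c run/config.yaml
```

which produces `qc.tsv`, `descriptives.tsv`, `snp_association.tsv`,
`gene_minp.tsv`, `haplowalk.tsv`, `blocks.tsv`, stratified tables and a
`manifest.yaml` recording the seed and parameters.

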