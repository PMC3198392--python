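# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the limits of what the test suite demonstrates.

## Study design assumed

A frequency-matched, multi-centre case-control study: binary disease
status, covariates (age, sex, study centre/country, BMI class, smoking,
hypertension, family history, vegetable and alcohol intake-frequency
scores), and unphased biallelic genotypes for tag SNPs assigned 5'→3' to
named gene regions. Genotypes are minor-allele counts 0/1/2 with an
explicit missing marker; the minor allele is defined by control-sample
frequency (ties broken lexicographically), since controls approximate the
source population. No genomic base-pair arithmetic is done: SNP order is
the array index within a gene.

## Quality control

Per SNP: call rate, duplicate-pair concordance (fraction of non-missing
agreeing calls across submitted duplicate pairs; undefined when no pair is
informative), Hardy–Weinberg 1-df Pearson chi-square in controls using the
sample allele frequency, and control minor-allele frequency. Default flag
thresholds: call rate < 0.98, HWE p < 0.05, MAF < 0.05. Failing SNPs are
flagged, not removed — exclusion is left to the analyst, since candidate
studies differ on this and removal is irreversible.

## Single-SNP models

Unconditional logistic regression fit by IRLS (convergence when the
log-likelihood changes by < 1e-8, at most 100 iterations, step-halving on
overshoot). Rank-deficient designs have aliased columns dropped with a
warning (QR with column pivoting); complete separation is detected by a
runaway coefficient (|β| > 15) and flagged as non-convergence with no
estimate reported for the affected term. The IRLS core is deliberately
in-package and array-level: the permutation engine (below) performs
hundreds of thousands of small refits, and the test suite verifies the
fitter against an independent maximum-likelihood implementation to ~1e-8.

Trend p-values are Wald tests (the ORs and CIs come from the same fit, so
Wald is the natural companion; score and LRT variants agree
asymptotically). Missing genotypes/covariates are handled by listwise
deletion — no imputation is modelled. Centre is the default adjustment
stratum; the covariate set is configurable (centre vs. country).
Confounder sensitivity reports `100·|β_adj − β_base|/|β_base|` with a ≥5%
flag and an absolute-difference fallback when the base coefficient is 0.

## Gene-level min-P permutation test

The gene statistic is the minimum per-SNP additive-model p-value. Inference
shuffles case/control labels within permutation strata (centre by default;
single-subject strata are skipped with a warning), keeping genotypes and
covariates attached to subjects, and recomputes the minimum identically:
`p_emp = (count + 1)/(B + 1)`. B defaults to 9,999 for reporting and 999
in experiments; every seed is explicit.

Two deliberate implementation choices:

- **Score statistic inside the permutation loop.** The per-SNP statistic
  minimised is the efficient score test for the dosage term adjusted for
  covariates. It needs only one covariate-only IRLS fit per permutation,
  shared across all SNPs of the gene, instead of one full fit per SNP per
  permutation; it is asymptotically equivalent to the Wald trend test the
  per-SNP tables report, and because observed and permuted data are
  processed identically the permutation comparison is exact regardless of
  the statistic's asymptotics. Permutation refits warm-start from the
  observed covariate fit, so a permutation that reproduces the observed
  labels reproduces the observed statistic bit for bit.
- **Mean-dosage imputation of missing genotypes inside the screen.** At
  ~2% missingness this perturbs the statistic negligibly and lets every
  SNP share one covariate fit; listwise deletion is retained in all
  reported per-SNP models.

The gene report shows the raw empirical p and its BH adjustment across
genes side by side, labelled unambiguously (published tables are sometimes
ambiguous about which "adjusted" value is meant).

## Haplotype engine

Frequencies over a 1–8 SNP window are estimated by EM under random mating
(E-step: posteriors over compatible ordered phase pairs ∝
`f(h₁)f(h₂)·(2 if h₁≠h₂)`; M-step: frequencies = expected counts / 2n).
Initialisation is the deterministic linkage-equilibrium product of
single-SNP allele frequencies; an optional multi-start (random Dirichlet
restarts with fixed sub-seeds, best likelihood kept) guards rare local
maxima. Convergence: log-likelihood change < 1e-8, max 500 iterations;
monotonicity is asserted at every iteration. Haplotypes ending below 1e-6
are dropped unless removal would orphan a genotype pattern. Subjects with
any missing genotype in the window are excluded (≤3% missingness makes
marginalising over missing alleles needless complexity).

Association is two-stage expectation substitution: phase posteriors are
estimated phenotype-blind on the pooled case+control sample, then
posterior-expected dosages of each non-reference haplotype enter the
logistic model (most frequent haplotype = reference; frequencies < 5%
pooled into one "rare" column; a pooling threshold above the reference
frequency is a configuration error). This is deterministic and matches the
documented behaviour of the classic haplotype-GLM approach. An optional
refinement mode re-weights phase posteriors by the outcome likelihood and
refits until coefficients change < 1e-6 (frequencies held fixed); it is
off by default and is a no-op when phase is unambiguous. Case/control
frequency columns are posterior expected counts split by group (the
alternative — separate EMs per group — gives slightly different columns
and would decouple the frequencies from the fitted model).

LD r² between two SNPs uses the two-locus EM frequencies among controls:
`D = f(ab) − f(a)f(b)` on minor alleles, `r² = D²/(f(a)(1−f(a))f(b)(1−f(b)))`.

## Haplowalk, blocks, strata

The haplowalk scans consecutive width-3 windows per gene (a gene with m
SNPs yields m−2 windows; genes with fewer than 3 SNPs are skipped with a
notice), FDR-adjusts global Wald p-values within gene (a study-wide switch
exists; within-gene matches the per-gene framing of the screen), and flags
adjusted p < 0.1. Window failures propagate as NaN and are excluded from
the FDR m-count. Block selection is **not** automated: the tool reports
flagged windows and the control-only LD matrix; the analyst names blocks
in the config — automated block-detection algorithms are out of scope.

Stratified analysis freezes the haplotype dictionary, reference, and phase
posteriors from the full-sample EM so all strata share comparable rows,
then refits the GLM per stratum (strata with fewer than 25 cases or 25
controls are reported NA). Interaction is tested by LRT comparing
full-sample models with and without haplotype-dosage × stratum products,
one haplotype at a time, with the stratum categorical (df = #strata − 1;
an ordinal-trend coding is available but categorical is the default since
no dose-response is presumed). Country heterogeneity uses the analogous
LRT with genotype/haplotype × country products. Single-SNP stratified rows
default to trend coding with a dominant-coding switch.

Tertiles are cut at the 1/3 and 2/3 empirical quantiles of *control*
values; all subjects are labelled, ties go to the lower stratum (the
convention is an implementation decision; the direction is immaterial for
the analyses here). Descriptive tables use uncorrected Pearson chi-square
(the Yates correction would not match the conventional large-sample
reporting this mirrors) and pooled-variance t-tests from summary
statistics.

## Synthetic cohort generator

The generator's defaults emulate a multi-centre Central/Eastern-European
renal-cell-carcinoma candidate-gene study:

- 777 cases / 1,035 controls across 4 centres (probabilities 0.0875 /
  0.1030 / 0.3115 / 0.4980, the realized case distribution); country ==
  centre in the synthetic design.
- 13 gene regions totalling 163 tag SNPs. Five gene sizes are fixed by the
  emulated design (SLC19A1 6, MTHFR 8, BHMT 13, MTR 9, GGH 6); the
  remaining 121 SNPs are allocated plausibly across the other eight genes.
  SLC19A1 and MTHFR carry fixed haplotype pools matching published control
  frequencies (the 4-SNP SLC19A1 block holds the risk haplotype A-C-C-C at
  6.4%); the other genes get randomly drawn block pools (blocks of 2–5
  SNPs, ≤6 haplotypes, pool MAF floor 0.075 so sampled control MAFs stay
  ≥5% at study size) from a fixed structure seed — pool shapes are a
  property of the emulated population, not of any one simulated cohort.
- LD arises solely from block pools combined at linkage equilibrium across
  blocks (no recombination model; the analysis operates within gene blocks
  only).
- Disease status is Bernoulli from a logistic model additive in haplotype
  copy number with covariate effects (age 0.005/yr, sex 0.05, small centre
  effects). The default risk model gives the A-C-C-C haplotype a per-copy
  log-OR of ln(1.163) plus ln(1.9/1.163) extra in the lowest
  vegetable-intake tertile, making the stratum ORs ≈ (1.9, 1.16, 1.16)
  and the marginal ≈ 1.37. Separate configs plant a homogeneous OR 1.37
  or a low-tertile-only ln(1.9) for the recovery experiments.
- Vegetable intake is a discrete frequency score, Binomial(18, 0.45), with
  population tertile cut-points from its CDF; alcohol is a zero-inflated
  score (24% non-drinkers). These are synthetic stand-ins: the emulated
  study only reports tertiles, not score distributions.
- Cases are sampled from the population until the quota is met; control
  covariates for the matching factors (age, sex, centre) are resampled
  jointly from the realized cases, approximating frequency matching, and
  controls are retained on status 0. The intercept (−0.6) only sets
  sampling efficiency — case-control ORs are invariant to it.
- Missingness is 2% completely at random. A fixed master seed makes the
  cohort bit-for-bit reproducible.

**What the generator does not emulate:** population stratification between
countries, informative missingness, genotyping batch effects, recombination
within blocks, correlation between diet and covariates, or measurement
error in the food-frequency scores. Passing tests therefore demonstrate
the statistical machinery is correct and calibrated under the stated
generating model — not that any particular real-data finding is robust to
those artefacts.

## Experiment sizes

Chosen as the smallest sizes at which the targeted properties are sharp:
null min-P calibration uses 500 genes at B=999 (type-I error standard
error ≈ 1%); CI-coverage of the planted OR 1.37 uses 200 study-scale
replicates; the stratified low-tertile pattern uses 120 replicates; the
acceptance script uses 100 / 60 replicates and a 200-gene, B=499
calibration. Recovery experiments simulate only the causal gene: the other
12 regions are independent of status by construction and do not affect the
block estimates.

## Known limitations

- Wald intervals (and the separation heuristic) degrade with sparse
  haplotype counts; no Firth or exact logistic fallback is provided.
- The EM excludes subjects missing any window genotype; a
  `marginalize_missing` policy is deliberately not implemented.
- Windows are limited to 8 SNPs (no partition-ligation EM).
- The permutation screen's score statistic and mean-imputation are
  asymptotic conveniences; at very small strata or extreme MAFs the
  reported per-SNP Wald p and the screen's score p can diverge.
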