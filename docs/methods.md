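# Methods

This note records the statistical procedures, default parameters and
design choices behind `polyrisk`, and what the synthetic data
generators can and cannot stand in for.

## Data model

Genotypes are minor-allele counts (0 = major homozygote, 1 =
heterozygote, 2 = minor homozygote, −1 = missing). Allele orientation
is fixed by the SNP manifest, never by observed frequency, so a minor
allele that is commoner among cases than controls keeps its label and
its odds ratio stays > 1. Missing genotypes are excluded pairwise per
statistic — no imputation; each MDR/CART model drops only the
individuals missing at its own loci.

## Quality screening

Controls are screened for Hardy-Weinberg equilibrium with the 1-df
Pearson χ² goodness-of-fit test against expectations from the sample
allele frequency, at α = 0.05. The exact conditional test is available
(`hwe_test(..., method="exact")`) but is not the default: the plain χ²
on control counts reproduces the intended screening outcome on the
embedded panel scale, and at these sample sizes the two agree closely.
Monomorphic SNPs fit HWE trivially and return p = 1.

## Single-locus statistics

* Allele tables count minor alleles as het + 2·minor-hom per group.
* OR orientation: case minor-allele odds over control minor-allele
  odds; the Woolf interval exp(ln OR ± z₀.₉₇₅·√(1/a+1/b+1/c+1/d)) is
  used throughout, including for MDR high-risk groups, CART node
  contrasts and GRS bins.
* Zero cells: with `correction="none"` the OR is reported undefined
  (as summary tables print a dash); `correction="haldane"` adds 0.5 to
  every cell. Tables with an entirely empty margin are undefined
  without the correction.
* p-values: Pearson χ² without continuity correction; Fisher's exact
  two-sided test replaces it on 2×2 tables when any expected count is
  below 5 (Cochran's criterion). On 2×k genotype tables the χ² keeps
  k−1 df (empty genotype columns are dropped).
* Bonferroni: min(1, p·m). The pipeline's default m is the number of
  SNPs *genotyped*, not the number surviving the HWE screen — the
  correction should pay for every test designed, and this matches how
  the embedded panel's published correction was computed (18, not 17).
* Power: two-sided two-proportion z-test normal approximation. The
  target OR is converted to the second group's proportion on the odds
  scale; the null SE uses the pooled proportion, the alternative SE
  the group-specific ones; both rejection tails are counted.
* The logistic interaction check compares main effects + all pairwise
  products against main effects only (likelihood-ratio χ², df = number
  of product terms), with dominant coding by default. Only pairwise
  products enter: fully saturated multi-way models on sparse genotype
  cells produce unstable estimates. Non-convergence or separation is
  returned as a flagged result, not an exception.
* `cv_auc_compare` fits the same design per stratified fold (near-MLE
  logistic regression) and reports mean training AUC, mean held-out
  AUC and their difference, as an over-fitting diagnostic for a
  selected SNP panel.

## MDR

A cell of the k-locus genotype table is high-risk when its
cases/controls ratio is ≥ T, where T defaults to the case:control
ratio of the training fold (the standard threshold for unbalanced
designs). Ties at exactly T are classed high, stated for determinism.
Cells unobserved in training are "empty" and predict low risk
(non-case) at evaluation time — the conservative convention,
switchable via `MDRSearchConfig.empty_cells_high`.

The search enumerates all C(m, k) locus subsets for each k. Folds are
stratified by phenotype and seeded. Within each fold the subset with
the highest *training* balanced accuracy wins (ties broken toward the
lexicographically earliest subset); the subset winning most folds is
reported, its CVC is that count, and its testing BA is the mean
held-out balanced accuracy across folds. CVC ties break by testing BA,
then lexicographic order; across orders k the reported model is the
highest-CVC, then highest-TBA, then smallest-k (parsimony) model.

Permutation testing shuffles phenotype labels, re-runs the full
order-k search per permutation, and reports
p = (1 + #{null TBA ≥ observed}) / (n_perm + 1). Note the null
distribution of the *searched* TBA carries selection optimism (mean
≈ 0.53 rather than 0.50 for 45 candidate pairs at n = 1500); the TBA
of a *fixed* subset under permuted labels is the unbiased chance-level
reference, exposed as `evaluate_subset`.

The high-risk-group odds ratio rebuilds the risk map on the full
dataset and contrasts high- vs low-risk membership in a 2×2.

## CART

Splits are binary groupings of one SNP's genotype categories; all
proper bipartitions of the observed categories are candidates (three
when all three genotypes are present), so dominant-, recessive- and
heterozygote-specific groupings compete on equal terms. The split
criterion is the decrease in total Gini impurity n·2p(1−p); ties break
by manifest order, then lexicographically smallest left set. Defaults
follow rpart conventions: min_split = 20, min_bucket = 7, cp = 0.01
(a split must improve by at least cp × root impurity), max_depth = 30.
Missing genotypes at a split follow the majority side; surrogate
splits are not implemented.

Pruning is weakest-link cost-complexity on misclassification risk.
`prune="cp"` collapses links weaker than cp × root error;
`prune="one-se"` (default) estimates the risk of each critical-α
subtree by stratified 10-fold cross-validation (re-growing the tree on
each training fold) and keeps the smallest subtree within one binomial
standard error of the minimum CV risk. Label-permuted data therefore
prunes to the root in most replicates.

Terminal nodes are ordered by case fraction; the lowest is the
reference for per-node odds ratios, and the Cochran-Armitage test with
node rank as score (two-sided, unconditional variance) tests the risk
trend. Published tree *shapes* from any particular study are treated
as qualitative targets only: they depend on exact hyperparameters and
CV partitions that are rarely reported.

## GRS

Unweighted additive score: 0/1/2 risk alleles per SNP, summed. Risk
allele = minor if allelic OR ≥ 1 (boundary inclusive), else major.
Orientation is, as in the source study, estimated on the analysis data
itself; this biases the case−control score difference upward
(in-sample optimism — verified by simulation in the test suite), so
externally validated effect sizes require an independent orientation
sample. Group comparisons use the equal-variance two-sample t-test;
per-subtype case groups are each compared against the same controls.
Binned analysis uses width-2 consecutive bins from the observed
minimum with optional pooling of all scores ≥ a cut (the embedded
panel's published contrast pools 19–26). The published "13 groups" do
not match 12 width-2 bins over 3–26; the binning is configurable and
the discrepancy is simply noted. Score 19 is placed in the pooled top
bin, matching the published "19–26" range.

In the pipeline the GRS is computed on the HWE-filtered panel. For the
embedded counts this reproduces the published group means (expected
12.12/11.45 vs published 12.08/11.46); summing the full 18-SNP panel
instead would shift both means up by ≈ 0.16, which is how the
filtered-panel convention was identified.

## Synthetic data

`simulate_hwe_genotypes` draws each SNP independently as
Binomial(2, MAF) — Hardy-Weinberg proportions, no linkage
disequilibrium. `simulate_case_control` composes disease odds as
baseline odds (default prevalence 0.3, chosen to keep
rejection-sampling acceptance practical while representing a common
late-life disease) × OR^(minor-allele count) per SNP × the odds of an
optional multi-locus penetrance table, then rejection-samples until
both groups are filled; the generative truth is returned alongside.
`epistatic_penetrance` provides two-locus XOR (high risk iff exactly
one locus carries a minor allele) and checkerboard (parity of code
sum; exactly zero marginal effects at MAF 0.5) tables. The epistasis
stress-test conditions are XOR penetrance 0.45/0.05 at MAF 0.3 with
750 cases/750 controls among 10 SNPs — two causal, eight noise — a
scale comparable to the motivating study.

`marginal_matched_dataset` reconstructs a cohort whose per-SNP,
per-group genotype counts equal supplied summary counts exactly, with
each SNP shuffled independently within group. Every single-SNP
statistic on such a cohort equals the count-derived value *exactly*;
the joint structure is random, so multi-locus results (MDR accuracies,
CART trees, GRS standard deviations and bin tails) do **not**
reproduce published interaction analyses — those require the
individual-level genotype file. Passing tests on synthetic cohorts
therefore validate the machinery and the marginal-determined
statistics, not the joint-structure findings. Real panels also carry
within-gene LD, which none of the generators emulate (an explicit
non-goal: the motivating panel used tag SNPs at r² ≤ 0.8).

## Known limitations

* No covariate adjustment (age/sex) in any stage; the reproduced
  tables are unadjusted.
* No surrogate splits, bagging or model-based MDR variants.
* The permutation test re-runs the full exhaustive search per
  permutation; at large m and k this is the dominant cost (it is
  vectorised per locus subset, but still C(m, k) × folds per
  permutation).
* The published allelic p-value of the panel's top SNP (printed 0.003)
  is not recovered by any standard 2×2 test on the printed counts
  (uncorrected χ² gives 0.0010, Yates 0.0013, Fisher 0.0010); the
  package reports the computed value and keeps the printed one only as
  the input of the Bonferroni arithmetic check (0.003 × 18 = 0.054).
* Two internal inconsistencies of the embedded panel are resolved in
  `polyrisk.panel`'s docstrings: one SNP's allele row disagrees with
  its genotype row (genotypes taken as authoritative), and one
  garbled genotype row is reconstructed from its percentages and
  allele counts.
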