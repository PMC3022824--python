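# Methods

`snpsib` implements a two-stage pipeline for predicting binary case-control
status from small subsets of SNP genotypes, built around two classifiers —
the sequential information bottleneck (sIB) and Fisher linear discriminant
analysis (LDA) — and one evaluation criterion, the harmonic mean of
sensitivity and specificity (HMSS).  This note records the models, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic study design does and does not establish.

## Data model and coding

Genotypes are biallelic and categorical: 0 = minor-allele homozygote,
1 = heterozygote, 2 = major-allele homozygote, with a missing sentinel.
The minor allele at each SNP is decided on the **training cohort only**
(frequency ties break to the alphabetically first allele) and that mapping
is frozen for the test cohort; likewise, missing calls are imputed with the
per-SNP majority category **computed on the training matrix** (ties to the
lowest code).  Both choices prevent test-cohort information from leaking
into the data representation.  The two cohorts play fixed roles: one is
used for all fitting and selection, the other exclusively for final
evaluation.

## HMSS and uncertainty

HMSS = 2·se·sp/(se+sp) weighs the two group accuracies equally and is
invariant to the case:control ratio, which matters because the cohorts are
imbalanced (58% cases in training, 38% in test).  It is taken to be 0 when
se = sp = 0, keeping the criterion total.  Confidence intervals come from a
**stratified percentile bootstrap**: (truth, prediction) pairs are resampled
with replacement within cases and controls separately (B = 200, 95% level,
linear interpolation between order statistics), with the classifier frozen.
Stratification guarantees both rates are defined on every resample; freezing
the classifier means the interval quantifies sampling noise of the
evaluation cohort, not refitting variability.  Cross-validation-side
intervals resample the pooled out-of-fold (truth, prediction) pairs under
the same scheme.  A coverage simulation in the test suite checks the
interval against a classifier of known accuracy (se = sp = 0.7, n = 100+100)
and observes ~94% empirical coverage at the nominal 95%.

## Sequential information bottleneck

Each training sample x is represented as a distribution p(y|x) over genotype
feature tokens (SNP, category): an s-SNP subset gives mass 1/s to the
observed category of each SNP, with a uniform prior p(x) = 1/n.  The method
seeks a hard K-cluster partition C minimizing

    L = I(C;X) − β·I(C;Y),

which for hard assignments and a uniform prior is H(C) − β·I(C;Y).  The
optimizer is the sequential scheme: random initial partition; repeated
sweeps in a seeded random sample order where each sample is drawn out of its
cluster and re-inserted into the cluster of least L (ties to the lowest
cluster index); a restart stops when a sweep makes no reassignment or after
`max_sweeps` = 50; the best of `n_restarts` = 10 restarts by final L wins.
L is non-increasing across every draw-and-reinsert step — asserted to 1e-9
in the tests — because re-insertion into the departed cluster restores L
exactly.  Clusters may empty and revive during sweeps; finally empty
clusters carry no label.

Classification is post-hoc: each non-empty cluster is labelled with its
majority training class (ties to control), and a new sample is routed to the
non-empty cluster minimizing the frozen insertion cost
(p_x + p_c)·JS_w(p(y|x), p(y|c)) with nominal mass p_x = 1/n_train and
weights w = (p_x, p_c)/(p_x + p_c), then receives that cluster's label.
The sweep optimizes ΔL exactly rather than the Jensen-Shannon merge-cost
surrogate; the two coincide in the uniform-mass limit used here.

**Choice of K.**  The description of the method leaves K open.  Setting
K = 2 to mirror the binary outcome turns out to be degenerate for genotype
tokens: the two-cluster optimum recovers a coarse genotype grouping
(typically isolating the modal category of the most informative SNP), and
with a case-majority training cohort both clusters are then usually
case-majority, collapsing the labelled classifier to "always case"
(HMSS = 0).  The default is therefore **K = min(3^s, 9, n)**, which resolves
every genotype cell for the 1- and 2-SNP subsets where the exhaustive
searches operate; majority labelling then acts as a genotype-cell majority
rule, which is also the natural reading of "label each cluster by its
dominant category" at full resolution.  K remains a parameter; K = 2 is
exercised in the brute-force oracle tests, where the sequential optimizer
attains the global two-block optimum on essentially every tiny instance.

**β.**  The default β = 10 puts the optimization in the relevance-dominated
regime (compression is a secondary concern at these K); results are
insensitive to β over a wide range because with K ≥ the number of occupied
patterns the relevance term saturates.

**Performance.**  Cluster token masses are integer multiples of 1/s, so the
sweep kernel (numba) keeps integer sufficient statistics, reads the
x·log2 x terms from lookup tables, and memoizes insertion/removal
evaluations per (genotype pattern, cluster), invalidating them only when a
cluster changes.  Both devices are exact: the sweep's decisions are
identical to direct evaluation.  This makes the ~60,000 sIB fits of a
cross-validated exhaustive pair search run in minutes on one core.

## Fisher LDA

The weight vector solves (S_w + λI)w = μ_case − μ_control with S_w the
unbiased pooled within-class covariance and λ = ε·tr(S_w)/d (ε = 1e-8),
escalated tenfold until the system solves; the threshold is the equal-prior
midpoint w·(μ_case + μ_control)/2, and boundary cases are called cases.
Genotype codes enter as real numbers.  On well-conditioned problems the
rule's predictions match a reference Fisher-discriminant implementation
with uniform priors, and the decision is invariant to affine rescaling of
any feature.

## Two-stage selection

**Filter.**  Every SNP is scored by the training (resubstitution) HMSS of a
single-feature LDA; the top k (default 1,000; 50 at desk scale) survive.
Ties break by smaller chi-square p, then rs-id — deterministic and
test-blind, like every tie-break in the package.

**Wrappers.**  Subsets are scored by the HMSS of pooled out-of-fold
predictions from a stratified, seeded 5-fold split of the training cohort
(pooling keeps both rates well defined even in thin folds; a single 4+1
split is available via `k_rotations=1`).  Forward selection greedily adds
the CV-HMSS-maximizing candidate.  SFFS starts from the exhaustive best
2-SNP subset and follows each inclusion with conditional exclusions that
must strictly beat the best-known criterion at the reduced size, keeping a
best-per-size table.  The exhaustive search evaluates all 1- and 2-SNP
subsets (larger sizes gated behind an explicit override).  The constrained
search maximizes cross-validated accuracy in one group over subsets whose
accuracy in the other group is at least 0.4, carries the top 20 to the test
cohort, and reports the best by test accuracy.  Test data reach a search
only for post-hoc reporting; a dedicated audit perturbs test labels and
verifies bit-identical selections.

## Synthetic study design

The generator emulates a two-cohort genome-wide case-control study: per-SNP
MAFs drawn uniform on [0.10, 0.50] (the emulated genotyping platform
targets common variants), Hardy-Weinberg genotypes, a logistic liability
P(case|g) = σ(α + Σ β_j g_j) with g counting minor alleles, and MCAR
missingness at 1%.  Individuals are drawn by rejection (genotype → label)
until the exact quota of each cohort is met — the analogue of quota-based
case-control ascertainment — so cohort composition is exact while the
genotype-phenotype dependence is preserved.  Defaults: 500 SNPs; cohorts of
941 cases/686 controls (training) and 443 cases/728 controls (test); two
causal SNPs with per-allele log-odds 1.1; baseline intercept −1.3 (keeps
the rejection sampler efficient for a ~50% draw rate); no intercept shift
between cohorts (one source population; the differing case fractions come
from the quotas).  The full 451,724-SNP panel size is available by setting
`n_snps`; it is not the default because the filter stage is
embarrassingly linear and the scientific behavior of the pipeline is
unchanged at 500 SNPs.  An optional block-LD mode (adjacent-SNP haplotype
copying) exists but is off by default, matching a method that never models
LD.

What the generator does **not** emulate: linkage disequilibrium structure
of real genomes (by default), population stratification and relatedness,
genotyping batch effects, informative missingness, and X-chromosome dosage.
Passing tests therefore establish internal correctness and statistical
calibration of the pipeline, not performance on real cohorts.

At these defaults the exhaustive 2-SNP sIB search recovers at least one
planted causal SNP and exceeds test HMSS 0.60 in at least 8 of 10 seeds
(recomputed by the test suite).  Null behavior differs by classifier in an
instructive way.  With labels permuted, LDA's forward-selected best subset
scores in the balanced chance band (mean test HMSS within [0.40, 0.60]
over 20 replicates), because a linear rule thresholded at the class-mean
midpoint keeps se + sp ≈ 1.  The sIB pipeline, by contrast, scores well
*below* 0.5 under the null (mean ≈ 0.30 at study scale): in a 58%-case
training cohort the dominant-class labelling marks most clusters "case",
predictions skew toward cases, and HMSS — which punishes se/sp imbalance —
drops accordingly.  This is faithful method behavior, not an artifact: the
same collapse appears for misaligned single SNPs in real-data analyses of
this design.  The test suite asserts the balanced band for the sIB null
pipeline as an external calibration expectation and documents its failure;
interpret sIB null performance as "below chance-band", not "0.5".

## Numerical conventions

Information quantities are in bits with 0·log 0 = 0; distributions are
validated to 1e-6.  The sIB objective reported by a fit is recomputed from
the final partition's exact integer statistics and agrees with an
independent evaluation to 1e-9.  Chi-square association uses the genotypic
Pearson test on the 2×r table without continuity correction, dropping
empty categories (df = r−1; a monomorphic SNP scores 0 with p = 1), since
the analysis is genotype-coded throughout.  Multiple testing uses the
Bonferroni cut-off α/m.  Every stochastic stage derives its seed from a
master seed plus a stable stage tag (crc32), and classifier seeds inside
searches derive from (base seed, subset, fold), so whole runs are
bit-reproducible from their echoed configuration.

## Known limitations

* The sIB insertion cost for unseen samples is a modelling choice (frozen
  JS cost with nominal mass 1/n_train); the method description is silent on
  test-time assignment.
* Bootstrap intervals do not account for refitting variability or for the
  selection process (subsets are chosen by maximizing CV HMSS, so their CV
  estimates are optimistically biased — visible in the null calibration's
  CV-vs-test gap; the design deliberately reproduces this property of the
  original analysis rather than nesting the selection).
* The filter stage considers SNPs one at a time, so purely epistatic pairs
  with null marginals can be lost before the wrapper stage.
* Desk-scale runtimes are minutes; a full 451,724-SNP filter is linear in m
  and memory-light, but the exhaustive pair search over 1,000 candidates
  (~500k subsets × 5 folds) is hours on one core.
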