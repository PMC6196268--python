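# Methods

`nksig` implements a two-group miRNA signature-discovery analysis for human
NK-cell subsets (CD56bright vs CD56dim), from raw array intensities to a
validated multivariate signature. This note records the models, the defaults
and the design choices that were genuinely open.

## Preprocessing

Raw linear-scale intensities pass through a fixed chain:

1. **Detection floor** — every value below 1 light unit (LU) is set to 1 LU.
   The floor guarantees positivity for the log transform and encodes the
   scanner's detection limit.
2. **log2 transform.**
3. **Quantile normalization** — each sample's empirical distribution is
   replaced by the mean distribution of order statistics across samples.
   Ties within a column receive the mean of the reference values over the
   tied rank span, the standard mean-of-order-statistics convention; this
   keeps the transform rank-preserving and makes column-sorted vectors
   identical to machine precision.
4. **Batch adjustment** — per feature, each batch's mean is shifted to the
   feature's grand mean (location-only). This is the simplest adjustment
   consistent with a two-batch design containing both phenotype groups in
   each batch; it preserves within-batch group contrasts exactly and is
   idempotent. Empirical-Bayes shrinkage (ComBat-style) is deliberately out
   of scope. A batch containing a single group is rejected: batch and
   phenotype would be confounded and the adjustment would erase biology.
5. **Median centering** (optional, for heat-map display) — subtract each
   feature's across-sample median.

The chain order (floor -> log2 -> quantile -> batch) follows standard
one-color array practice. **Detection calls** are made on the normalized
log2 table: a feature is detected in a sample when its value exceeds the
threshold (default 1 LU on the log2 scale, matching how detection counts
are reported downstream of normalization; a flag allows linear-scale
thresholding), and "detected in half or more" of a group means at least
`ceil(0.5 * n)` of its samples.

## Univariate differential expression

Per feature, a two-sample test on log2 values between the groups: Welch's
t-test by default (the conventional microarray choice when the vendor tool's
internal test is unknown), Mann-Whitney by flag (exact enumeration with
mid-ranks when both groups have <= 8 samples, normal approximation
otherwise). Features failing the detection filter in both groups are
excluded *before* testing and multiplicity adjustment. Adjustment is
Benjamini-Hochberg by default, Bonferroni by flag.

The effect size is the difference of group medians on the log2 scale
(`delta = median(dim) - median(bright)`), reported also as a signed fold
change `sign(delta) * 2^|delta|`. Classification: **induced** when
`p_adj <= 0.05` and `delta >= 1` (two-fold up in dim), **repressed** when
`p_adj <= 0.05` and `delta <= -1`, otherwise unchanged. Pairing of donors is
recorded in the metadata but not used by the test, because the
signature-calling criteria are defined on unpaired group statistics.

Bi-clustering for the signature heat map runs agglomerative clustering
independently on features and samples; default distance is 1 - Pearson
correlation with average linkage (the common display default; Euclidean and
complete linkage selectable). Items are pre-sorted lexicographically so
equal-distance merges resolve deterministically.

## The l1l2 sparse classifier

The multivariate engine is a linear model f(x) = beta . x + b, classified by
sign(f), trained by minimizing

    (1/n) ||y - X beta - b||^2 + tau ||beta||_1 + mu ||beta||_2^2

on per-feature z-scored inputs (training statistics only; intercept
unpenalized, hence b = mean(y) with centered columns). Square loss on +/-1
labels was chosen over logistic loss because the validation stage explicitly
uses regularized least squares; tau = 0 reduces the fit to exactly that
ridge estimator, computed in closed form (via the dual when d > n). The l1
term produces exact zeros (variable selection); the l2 term spreads weight
across correlated discriminative features instead of picking one
arbitrarily.

Solver: FISTA with backtracking line search and a function-value restart
(which keeps the recorded objective non-increasing), soft-thresholding as
the proximal step. Convergence requires both the relative objective change
and the relative iterate change to drop below `tol` (default 1e-6; the
objective criterion alone cannot resolve parameter accuracy near the
optimum in floating point), followed by a short plain proximal-gradient
polish whose fixed point is the exact minimizer. Ties in the sign rule map
to the positive class (documented and tested). `tau_max = 2 ||Z'yc||_inf /n`
gives the smallest tau with an all-zero solution; the automatic tau grid is
geometric from `tau_max` down to `tau_max/20` (10 points), warm-started
along the path. The grid floor deliberately stays above the regime where,
at n << d, the lasso active set saturates and its size becomes erratically
data-dependent (probing lower floors produced 160- vs 886-feature
minimizers on splits of the same dataset).

## Nested cross-validation and stability aggregation

Model selection and accuracy assessment are separated into two nested
loops:

- **Outer:** B = 5 stratified Monte-Carlo learning/test splits (25% of each
  class in the test set, drawn without replacement, seeded). A
  `pair_by_donor` option assigns whole donors to the test side so paired
  samples never straddle a split (off by default; the signature criteria are
  unpaired).
- **Inner:** on each learning set, 4-fold stratified CV over the tau grid.
  The l2 weight is **fixed** by default at 1e-2 x the spectral scale
  (sigma_max^2/n of the centered learning matrix), following the method's
  convention of fixing the correlation parameter and cross-validating only
  the sparsity parameter; a mu grid can be supplied, in which case the
  inner CV scans (tau, mu) jointly. The pair with minimal mean inner error
  wins; ties resolve toward **smaller tau, then smaller mu**. Both choices
  matter and were settled empirically: with strongly separable data nearly
  every penalty pair reaches zero inner error, so CV cannot identify mu at
  all, and the tau tie-break decides the model. Preferring sparsity
  (larger tau) would discard exactly the correlated feature groups the l2
  term exists to retain; preferring the smallest tau keeps them, and the
  fixed mid-scale mu stabilizes *which* correlated features the per-split
  lasso paths keep, so the 50% frequency cutoff reliably recovers the full
  planted set. At the study scale this yields aggregated signatures of
  roughly 35-50 of 2000 features with zero outer error.

The winning pair is refit on the full learning set; the non-zero features
form that split's list and the test error is recorded. Mean accuracy is the
average over the B test sets. The aggregated signature keeps features
selected in at least phi = 50% of the lists, ordered by frequency, then
mean |beta|, then name; the full count-vs-frequency curve is exposed as a
diagnostic for the cutoff. Standardization and penalty selection see only
learning-fold data — no test-set leakage, which the permuted-label canary
checks (chance accuracy when labels are shuffled).

## Validation

A reduced signature (e.g. 12 miRNAs) is assessed by Monte-Carlo
cross-validation: R = 100 stratified random 75/25 splits, ridge classifier
(mu = 0.1) per split, test accuracy per split. The same procedure with
labels permuted per repetition yields the null distribution, and a
two-sided two-sample Kolmogorov-Smirnov test compares the two accuracy
samples (exact method when both have <= 25 observations, asymptotic
otherwise). Because accuracy on small test sets is heavily tied, the KS
test is conservative under the null — its p-values are stochastically
larger than uniform — so a significant result is trustworthy while the
null rejection rate sits below the nominal level; the calibration test
bounds it within binomial error of 0.05.

**Cross-technology prediction:** qPCR measurements enter as -dCt per
feature (log2-like, rising with abundance), are z-scored per feature
*within the new cohort* — removing platform location and scale without
paired calibration samples — and classified by the model's sign rule.
Zero-variance features in the new cohort cannot be harmonized and are
dropped with a warning.

## qPCR and reporter arithmetic

Comparative-Ct quantification: replicate Ct values are averaged on the Ct
scale; dCt = mean Ct(target) - mean Ct(reference gene) per sample (RNU6B
for miRNA, GAPDH for mRNA); ddCt = dCt(sample) - dCt(calibrator), where a
group calibrator uses the unweighted mean dCt over its members; relative
quantity RQ = 2^-ddCt. No amplification-efficiency correction and no
replicate-outlier filtering. Dual-reporter assays: firefly/renilla ratio
per well, normalized to the control-group mean ratio (control mean exactly
1). Group comparisons use Welch's t, Mann-Whitney, or one-way ANOVA with
Bonferroni-adjusted pairwise post tests on the pooled error term.

## Enrichment

Over-representation by the upper-tail hypergeometric distribution:
signature and pathways are intersected with a user-supplied reference
universe, pathways overlapping the signature in fewer than 3 genes are
excluded from testing *and* from the Bonferroni factor m, and significance
is `p_adj <= 0.05`. The enrichment ratio (k/n)/(K/N) exceeds 1 exactly when
the signature's pathway fraction beats the reference's. The score
`-log10(p_adj)` ranks pathways. miRNA-to-gene mapping goes through
user-supplied prediction tables (miRNA, gene, tool) aggregated with a
per-pair supporting-tool count and an optional minimum-support filter; no
live queries to prediction services.

## Synthetic data

The generator emulates the study design so every stage is testable offline:

- 10 donors, each contributing one bright and one dim sample (n = 20);
  optional Gaussian donor intercept (default 0) to exercise pairing.
- 2000 features; 250 expressed. Expressed baselines are Gaussian on the
  log2 scale (log-normal intensities, mean 5.5, sd 1.2) — soft tails like
  real array intensity distributions. A hard-bounded (uniform) baseline was
  rejected: it piles shifted features onto the extreme ranks, where quantile
  normalization compresses genuine differences into artifactual misses.
  Background features sit below the 1 LU floor (uniform log2 in [-2, 0.5]).
- 15 up- and 15 down-regulated features at +/-1.5 log2 in the dim group
  (comfortably past the two-fold calling threshold, at 5 sigma of the
  measurement noise); 2 features per group expressed exclusively (below the
  floor in the other group).
- Two batches, both containing both groups, the second offset by +0.5 log2;
  Gaussian log2 noise sigma = 0.3.
- The qPCR generator produces triplicate Ct values (baseline 30 cycles,
  replicate sd 0.15, RNU6B reference at 25 cycles) with dim-group Ct
  lowered by the planted log2 effect.
- An optional intermediate group (CD56bright/CD16dim-like) has per-feature
  means at a convex combination (default halfway) of the two group means,
  for the three-group maturation-trend ANOVA.

What the generator does **not** emulate: probe-level/scanner artifacts,
heavy-tailed spike-ins, donor-specific batch interactions, non-additive
batch effects, and cross-hybridization. Passing tests therefore demonstrate
correctness of the statistical machinery under a clean log-normal model,
not robustness to every artifact of real arrays.

## Problem sizes in the test and acceptance suites

The property suites run at two scales chosen to keep iteration fast while
preserving the study's structure: the full 2000-feature design for
end-to-end recovery and detection counts, and a 200-feature reduction (60
expressed, 5 planted) for the repeated-seed stability and pipeline tests.
Monte-Carlo validation uses R = 100 + 100 repetitions; the null-calibration
suite uses 200 repetitions of paired permuted-label arms.

## Known limitations

- The GEO series-matrix reader is best-effort for group/batch inference
  from characteristics lines; an explicit metadata table always wins.
- Quantile normalization attenuates very large fold changes when a
  noticeable fraction of features is differential; with ~15% of expressed
  features shifted, realized median deltas shrink by roughly 5-15%. This is
  a property of the method, not a bug, and mirrors what happens on real
  data normalized the same way.
- The KS null is conservative under tied accuracy distributions (see
  Validation above).
- Signature sizes from stability selection depend on the tie-break among
  zero-error penalty pairs; the chosen rule (smallest tau on the grid)
  trades minimality for stability of recovery.
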