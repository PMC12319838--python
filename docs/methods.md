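# Methods

## Problem and model

Curated clinical research MRI cohorts are quality-controlled before analysis:
each T1-weighted scan is accepted or rejected, traditionally by visual
inspection. Two automated tools are widely used as substitutes — MRIQC, which
extracts image quality metrics (IQMs) from the raw image and ships a
pre-trained classifier emitting a reject probability in [0, 1], and CAT12,
whose segmentation pipeline grades each scan on a 16-level weighted-IQR letter
scale from A+ (excellent) to F (failed). Neither tool was trained on elderly
or clinical populations, and their agreement with visual QC on such cohorts is
modest. `t1qc` implements a prediction framework that treats the two tools'
numeric outputs (68 MRIQC IQMs + 36 CAT12 quality measures = 104 features per
scan) as a feature vector and learns the visual accept/reject decision
directly, together with the agreement, correlation, and site-effect analyses
that surround such a framework.

The classifier is a random-undersampling boosting (RUSBoost) ensemble, built
from scratch here because the rebalancing rule is the core of the method.
Reject scans are rare (typically 5–10% of a curated cohort), so each boosting
cycle first draws a balanced training subset: all minority-class rows plus a
without-replacement sample of the majority class of equal size, sampled with
probability proportional to the current boosting weights (a uniform-sampling
switch is provided; published RUSBoost descriptions do not pin this choice
down, so weighted sampling — the variant that respects the boosting
distribution — is the default). A depth-limited CART tree (at most
`max_splits` internal splits, implemented as a `max_splits + 1` leaf cap) is
fitted to the subset; its weighted error ε_t is computed on the *full*
training set; cycles with ε_t ≥ 0.5 are discarded and resampled (up to 10
retries, after which boosting stops early). The cycle weight is

    α_t = η · ½ · ln((1 − ε_t) / ε_t)

with shrinkage η (the learning rate) multiplied into α, ε_t floored at
1/(2n) when a cycle is perfect, and the usual multiplicative AdaBoost update
w_i ← w_i · exp(−α_t y_i h_t(x_i)) with renormalisation. The ensemble score
is Σ_t α_t h_t(x) with h_t ∈ {−1, +1} (+1 = reject); a score of exactly 0
resolves to reject, because the framework's operating point deliberately
favours catching poor-quality scans at the cost of extra manual review.
SVM and bagged-tree random-forest baselines (scikit-learn `SVC` /
`RandomForestClassifier` with the same split cap) sit behind the same
interface, with hyperparameter grids: RUS — max splits {10, 50}, cycles
{10, 50, 100}, learning rate {0.01, 0.1}; RF — the first two of those; SVM —
box constraint {0.01, 0.1, 1, 10, 100, 1000} × {linear, rbf} kernels.

## Training protocol

Scans are split 80/20 into training and holdout, stratified jointly by label,
site, and diagnosis group, using largest-remainder rounding per stratum
(single-member strata go to training with a warning). Features are
z-score-normalised per site; means and standard deviations are always
estimated on training rows only and applied unchanged to evaluation rows.
Zero-variance features are guarded to σ = 1 (they become uninformative
zeros); sites with fewer than two training rows, and any site unseen at
training time (e.g. a held-out site), fall back to the pooled all-training
statistics — test data never contributes to normalisation.

Feature relevance is scored by four rankers — |two-sample t| and |AUC − ½|
(univariate; the two standard complementary parametric/nonparametric
choices), ReliefF (k = 10 nearest hits/misses on range-normalised Manhattan
distance, equal-influence weighting, k clipped to the available neighbours),
and greedy mRMR (mutual-information difference on 10-bin quantile-discretised
features). The four rank lists are combined by robust rank aggregation: for
each feature the normalised ranks r = rank/n across the m lists are sorted
and compared against uniform order statistics,

    ρ = min_k P(Beta(k, m − k + 1) ≤ r_(k)),

features are ordered by ascending ρ (ties broken by mean input rank, then
name), and a Bonferroni-adjusted ρ is reported. ReliefF's k, mRMR's
discretisation, and rank-based (rather than score-based) aggregation inputs
are package defaults, documented rather than inherited from any reference.

Model selection runs a repeated nested cross-validation: 5 outer × 3 inner
stratified folds (stratified by label × site when every stratum can fill the
folds, else by label), repeated over iterations with per-iteration fold
seeds `base_seed + i`. Normalisation and ranking are re-fitted inside every
training side, including each inner-fold training side. For each feature
size in the sweep {10, 20, …, 100, 104} the inner folds grid-search the
hyperparameters by mean inner balanced accuracy — ties prefer smaller models
(fewer cycles, then fewer splits, then lower learning rate; for SVM, linear
before rbf, then smaller box constraint) — and the outer fold is evaluated
with the selection. Fold-level aggregated rankings are pooled across all
outer folds and iterations by a second level of robust rank aggregation into
the final feature ordering; the per-size hyperparameters reported are the
modal inner choices. The final model refits all training data at each
feature size and reports the size maximising holdout balanced accuracy.

Performance metrics follow the convention that *accept* is the positive
class: sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), balanced accuracy
= their mean, FPR = FP/(FP+TN). Ratios with empty denominators (e.g. a test
group with no rejects) are *undefined*, propagate as NaN, and are excluded
from group means — never coerced to zero.

## Generalisation experiments

The additional experiments inherit the combined model's hyperparameters,
feature ranking, and feature size rather than re-optimising (a from-scratch
mode is available by simply re-running the nested CV on the reduced data):

- **Leave-one-site-out** — each site in turn is held out; training
  statistics come from the remaining sites and the held-out site is
  normalised with pooled training statistics. Sites with single-class test
  labels have undefined balanced accuracy and are excluded from the mean.
- **Group splits** — train/test defined by metadata filters (field
  strength, manufacturer), with per-manufacturer and per-field-strength
  breakdowns of the test metrics.
- **Incremental inclusion** — a label-stratified fraction of a new cohort
  (per-class round-half-up, at least one row per class present) is added to
  training and the remainder of the new cohort is evaluated, tracing a
  learning curve over fractions.

## Agreement and diagnostics

Tool ratings are binarised by threshold schemes: MRIQC rejects at
probability ≥ 0.4/0.5/0.6 (strict/default/lenient) and CAT12 rejects at
grade ≤ C / C− / D+ respectively; accept rates are therefore monotone from
strict to lenient by construction. Agreement between raters uses Cohen's
unweighted kappa with the large-sample p-value computed from the standard
error under the independence null (the convention of IRR packages); an
exact permutation p conditional on both margins is available for small n.
Cross-tool measure relationships use Pearson correlation with Fisher-z 95%
confidence intervals (requiring ≥ 4 complete pairs). Site-distribution
diagnostics run two-sample Kolmogorov–Smirnov tests for every feature and
site pair (asymptotic p-values, exact when both samples have n < 25) with
Bonferroni correction over the full number of comparisons.

## Synthetic cohorts

The generator emulates the statistical structure the framework assumes, so
every stage is testable without any data download. Features are Gaussian
with per-site additive offsets δ_sj ~ N(0, site_shift_sd²) and
multiplicative scales γ_s ~ U(site_scale_range) — the simplest structure
reproducing the site-wise density shifts seen in real multi-site QC tables.
Labels are per-site Bernoulli draws; a planted, contiguous subset of
features is shifted by `effect_size`·σ in the reject class so tests can name
the informative set. A latent quality score q (accept ~ N(0,1), reject ~
N(2,1); higher is worse) drives the simulated tool ratings: the MRIQC-style
probability is logistic(2·(q − 1) + ε) and the CAT12-style grade bins q + ε
into 16 evenly spaced intervals over [−2, 4], with rating noise sd 0.8 —
chosen so that simulated tool-vs-visual kappas land in the 0.2–0.4 range
typical of automated-vs-visual QC comparisons. Defaults mirror the
conditions the framework targets: 6 sites × 300 scans (N = 1800), 7.2%
reject prevalence, 104 features named after the merged MRIQC+CAT12 schema,
20 informative at effect size 1.0, site shift sd 0.5, scale range
(0.8, 1.25).

What the generator does *not* model: real IQM marginals (heavy tails,
boundedness, discreteness of size/spacing fields), correlated features,
label noise from subjective raters, and site-by-class interactions. Passing
tests therefore demonstrate that the pipeline recovers planted structure
under its own assumptions — not that the reported accuracies transfer to any
real cohort.

## Problem sizes and numerical choices

The test suite and the acceptance script run the nested CV at the protocol's
5 × 3 fold structure but with 2 repetitions, a reduced grid (max splits 10,
cycles {20, 50}, learning rate 0.1), and a 5-point feature-size sweep
{10, 20, 40, 80, 104}; this keeps the full pipeline to a couple of minutes
on one core while exercising every code path. The repetition count is the
knob to raise for precise performance estimates. Other numerical choices:
σ floor 10⁻¹² for zero-variance guards; ties in rankings broken by score
then lexicographic name; deterministic seeds derived arithmetically from a
single base seed everywhere (fold shuffles, undersampling, tree building,
incremental sampling), so every result in the package is exactly
reproducible from that seed.

## Known limitations

- The MRIQC (68) and CAT12 (36) default schemas are reconstructions of the
  standard output sets; deployments whose tool versions emit different
  field sets should pass their own schema lists to the readers.
- CAT12's native `.mat` container is not parsed; the reader consumes a
  flattened one-row-per-scan CSV/TSV export.
- Scans with any missing feature are excluded (and logged), not imputed.
- Kappa is unweighted binary only; no multi-category or weighted variants.
- Baseline SVM/RF models are not serialised to JSON (only the RUSBoost
  ensemble has a portable representation).
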