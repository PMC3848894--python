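# Methods

## The model

`comimod` predicts a binary prognosis (good = event-free past a follow-up
threshold, bad = event within it; five years by default) from a genes ×
samples expression matrix plus two gene-set collections: miRNA target sets
and GO biological-process (GO-BP) terms, both in GMT format.

### CoMi activity

For a miRNA–term pair, a sample's context-specific miRNA (CoMi) activity is
the Welch unequal-variance t statistic contrasting expression of the
miRNA's targets inside the term with the term's non-targets, positive when
targets exceed non-targets. The statistic is computed exactly as written
(sample variances, n−1 denominators); no pooled-variance option is offered
because the unequal-variance form is the definition.

Pair filtering happens before any scoring and uses no labels:

1. the target/term intersection must contain at least `min_intersection`
   (10) genes;
2. the intersection must be hypergeometrically significant at `alpha`
   (0.05). The universe M is the set of genes both measured and present in
   the union of the GO collection — the test should only count genes that
   could actually have been drawn;
3. at least `min_nontargets` (3) term genes must be non-targets. This guard
   is ours: the t statistic needs a variance from each group, and a miRNA
   targeting nearly the whole term is otherwise degenerate.

The tail probability P(X ≥ x) is computed with exact integer arithmetic
(binomial-coefficient recurrence, one correctly rounded division at the
end), so it is exact to double precision for any realistic universe; the
test suite checks it exhaustively against direct enumeration for all
universes up to 60 genes and against `scipy.stats.hypergeom` on larger
random configurations.

### Profile filtering

Rows (features) of the CoMi profile are noise-reduced in two steps: the
`floor(0.10 × rows)` rows with the smallest variance across samples are
dropped (ties keep the earlier row), then rows bitwise-identical to an
earlier survivor are removed, keeping the first occurrence. Bitwise
equality is deliberate — duplicates arise when two miRNAs have identical
target/term intersections, which produce identical columns, not
approximately equal ones. Feature order (miRNAs in target-GMT order outer,
terms in GO-GMT order inner) fixes the "first row" tie rule
deterministically. The filter is fit on training data only; the surviving
feature list is frozen and applied verbatim to any test cohort
(`comi score --features`).

### Modules, weak classifiers, ensemble

Features sharing a GO term form a module, named by the term; modules need
more than five miRNAs (≥ 6; `--min-module-size` resolves the alternative
"at least five" reading). Each module trains a nearest-centroid classifier
on its CoMi rows. Decision value y = ⟨s − (C₊+C₋)/2, C₊−C₋⟩; y > 0 assigns
the positive (good) class, and y = 0 goes to the negative class, following
the "otherwise negative" rule literally. No internal standardization is
applied to the CoMi scores.

Module selection: stratified five-fold cross-validation with one shared
fold assignment (fixed by the seed) for every module, pooling out-of-fold
decision values into a single AUC per module. Pooling (rather than
averaging per-fold AUCs) is more stable with five folds and imbalanced
classes. Modules at AUC ≥ 0.6 are selected and refit on all training
samples. The ensemble prediction is the majority vote; the vote fraction
serves as the continuous score for ROC construction. An exact tie
(possible with an even number of voters) is resolved by the sign of the
summed decision values, zero again going to the negative class.

### Evaluation

AUC is the Mann–Whitney probability that a positive-class score outranks a
negative-class one with ties half-credited — required because vote
fractions are discrete. MCC uses the closed formula with the convention
that any zero marginal gives 0. The repeated-CV harness refits the entire
pipeline (variance filter, module building, selection) inside every
training fold; the original protocol in which modules are selected once on
the full cohort and then cross-validated can be reproduced by passing a
frozen module list (`EnsemblePipeline(frozen_modules=...)`), but it leaks
selection information and is not the default.

### Significance of module sets

*Specificity*: the selected modules' test-cohort AUC is compared with
B = 10,000 ensembles built from equally many modules drawn uniformly
without replacement from all modules (no AUC screen for the null draws —
the random set stands in for the selected set as-is; draws come from the
full pool). The empirical p uses the add-one estimator
(1 + #{null ≥ observed}) / (B + 1) and never reports exactly zero.

*Stability*: two independently selected module-id sets are scored by the
upper-tail hypergeometric probability of their overlap within the shared
module universe, plus the overlap percentages of either set. The reference
configuration — 33 common modules between selections of 55 and 98 from 347
— gives p = 6.40e-08.

### Baselines

Flat top-k centroid classifiers on miRNA, mRNA, CoMi or set-statistic
features: features are ranked once by |w| from a full-training-data
centroid fit (a stricter `rank_in_fold` mode re-ranks inside each fold),
k sweeps 1–200 with shared CV folds, and the best pooled-OOF AUC wins, ties
to the smallest k. Set-median / set-mean features summarize each gene set
per sample by the median or mean of its measured members (sets with fewer
than two measured members are dropped). The published 70-gene and 76-gene
signatures need external gene lists and fitted coefficients and are out of
scope.

## The synthetic cohort generator

The generator emulates the method's own causal assumption: several miRNAs
co-regulate a biological process, and in bad-outcome patients the targets
inside that process are repressed relative to the term's other genes.

Defaults (the reference cohort): 3,000 genes, 112 miRNAs, 40 terms of
110–130 genes, 8 planted modules of 6 miRNAs, per-pair constructed
intersections of 12 genes, 50–70 targets per miRNA, effect size δ = 1.5 in
units of the unit noise sd, 100 samples per class (held-out cohorts default
to 50 + 50). Background expression is i.i.d. Normal(7, 1) on a log-like
scale.

Three structural choices matter and were made deliberately:

- **Constructed intersections.** Member miRNA–term intersections are built
  as disjoint blocks inside each term and sized so they pass the x ≥ 10 and
  p ≤ 0.05 screens with margin for the default universe; nothing about
  survival of the planted pairs is left to sampling luck. Non-planted terms
  get equally constructed (but unshifted) member miRNAs so that false
  module selection has a well-populated denominator.
- **Stratified gene space.** Planted terms occupy disjoint gene strata and
  background terms draw from a separate pool. The class shift is applied to
  genes, so any term sharing genes with a planted term would inherit a
  target-vs-non-target imbalance and stop being null; without
  stratification essentially every module becomes (genuinely)
  discriminative and false-selection rates are meaningless.
- **Term-level offsets.** Every term adds a per-sample Normal(0, 2) offset
  shared by all its genes. The offset cancels exactly inside the
  within-term CoMi contrast but inflates each annotated gene's marginal
  variance, so the planted signal is efficiently detectable as a
  within-term contrast and only weakly as a marginal gene effect — the
  regime the module method is designed for, and the reason the CoMi feature
  space outperforms raw mRNA features on these cohorts.

What the generator does *not* emulate: batch effects and other microarray
artifacts, probe-level structure, heavy-tailed noise, correlated outcomes,
survival times beyond the binary label, and target-prediction error beyond
what the random non-member overlaps produce. Passing the recovery tests
therefore shows the pipeline is correct and well-calibrated under its own
assumptions, not that it will reach any particular accuracy on real
cohorts; the published cohort-level AUC/MCC figures depend on external data
and databases and are documented, not reproduced.

## Numerical and degenerate-input policy

- Missing expression values are ignored pairwise inside the t statistic; a
  gene missing in over half the samples is dropped at load. A feature with
  fewer than two usable values in either group for some sample — or a zero
  pooled standard error with unequal means — is marked missing for that
  sample and dropped from the profile with a logged count (infinities would
  poison centroids); zero standard error with equal means scores 0.
- Variance uses the sample (n−1) form throughout; the 10% cut ranks
  identically under either convention.
- Empirical p-values are never 0 (add-one estimator); hypergeometric tails
  are exact integer arithmetic.
- All randomness (fold assignment, resampling, simulation) flows from
  explicit integer seeds; repeated runs are bit-identical, and model
  archives serialize floats losslessly (hex) so save/load preserves
  predictions exactly.

## Problem sizes used by the checks

The test suite's end-to-end checks run the reference cohort (200 training
and 100–200 held-out samples) over 20 seeds for planted-module recovery,
5 whole-dataset label permutations for null calibration, and 100 repeats of
the specificity test at B = 200 for p-value uniformity; the exhaustive
hypergeometric comparison covers every configuration with a universe of at
most 60 genes. These sizes make the full suite complete in well under a
minute per heavy check while leaving the statistical conclusions
comfortably clear of their thresholds.

## Known limitations

- GO terms are flat sets; no DAG propagation.
- Inputs are assumed gene-level; probe collapsing is the caller's job.
- The centroid classifier offers no shrinkage or probability calibration.
- Weighted voting and stacking are out of scope; the ensemble is the plain
  majority vote the method defines.
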