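# Methods

## The selection problem

Two-class expression studies (tumour vs. normal) typically provide tens of
samples and tens of thousands of genes. Identifying a small, robust set of
class-separating genes under that sample-to-feature ratio is a feature
selection problem: a filter stage must remove the bulk of uninformative
genes cheaply, and a model-based stage must then search the survivors for a
compact subset that actually classifies. This package implements that
two-layer scheme — a Fisher-score filter followed by recursive feature
elimination (RFE) around logistic regression — plus a consensus stage that
keeps only genes recurring across repeated runs or across datasets.

## Filter layer

For gene *i* with classes *k = 1..c* (here *c* = 2), class sizes *n_k*,
class means *μ_k*, overall mean *μ*:

    F_i = Σ_k n_k (μ_k − μ)² / Σ_k n_k σ_k²

with population variances σ_k². This class-weighted within-class
denominator is the standard Fisher-score form and is the default; a
`pooled` option divides by the whole-dataset variance of the gene instead,
a literal reading occasionally used in applied work. For a two-class
balanced design the two differ by a monotone transformation, so rankings
are usually similar but not identical.

Degenerate genes: if both numerator and denominator vanish (a constant
gene) the score is 0; if only the denominator vanishes the score is
`numerator / 1e-12`, capped at 1e15, so perfectly separating zero-variance
genes sort to the top without producing infinities.

**Elbow cut.** Genes are sorted by descending score (ties broken by gene
id, so the ranking is deterministic) and the list is cut at the inflection
point of the score curve. "Inflection point" is operationalized as the
max-chord-distance (elbow/knee) rule: min–max normalize both axes, draw the
chord from the first to the last point, and cut at the point with maximal
perpendicular distance to the chord. The cut is clamped into
`[min_keep, max_keep]` (defaults 50 and 4000 — the range within which
post-filter dimensionalities of typical two-class microarray datasets
fall), and a `keep` override supports manual cuts, since elbow choice on
real score curves legitimately involves judgment. An exactly linear or
constant curve has zero chord distance everywhere and falls back to
`min_keep`.

## Embedded layer

**Classifier.** Binary logistic regression written from first principles:
`a = σ(Xw + b)` with the numerically-stabilized logistic function (inputs
clipped to ±700, outputs kept strictly inside (0, 1)), trained by
full-batch gradient descent on the mean cross-entropy

    J(w, b) = (1/m) Σ_i −[ y_i ln a_i + (1 − y_i) ln(1 − a_i) ]  (+ l2‖w‖²/2).

The optional L2 penalty is *not* divided by m, so duplicating every sample
leaves the optimum unchanged (the data term is a mean). Defaults: step
size 0.1, up to 2000 iterations, stop when the cost improvement falls
below 1e-7, probability clip 1e-12, no penalty. A fixed step can diverge
on wide standardized matrices, so whenever a step would increase the cost
the step size is halved before retrying; this deterministic backtracking
guarantees the non-increasing cost trace that the model object enforces
(violations raise).

**Cross-validation.** Stratified K-fold (default K = 4, the conventional
worked value for this pipeline): each class is shuffled with the run seed
and dealt round-robin, so fold sizes differ by at most one overall and
within each class. Features are z-scored with training-fold statistics
only and those statistics are applied to the held-out fold — validation
data never influence the scaling.

**RFE.** Starting from the post-filter matrix, each step fits the
classifier on every training fold, records the pooled out-of-fold
accuracy/F1 of the surviving set, ranks features by the mean absolute
standardized weight across folds (the canonical linear-model importance),
and drops the `pace` weakest; the last step drops fewer to land exactly on
the floor. Pace is keyed to the post-filter dimensionality d1: 5 above
2000, 3 in (1000, 2000], 2 at or below 1000 — boundary values resolve to
the finer pace. On importance ties the lexicographically larger gene id is
dropped first, so the smaller id survives and the path is deterministic.

**Subset choice.** With `target_dim` set (default 78, the conventional
standard dimensionality for fixed-size cross-method comparisons), the
floor equals `target_dim` and the final, floor-sized step is selected, so
the subset size is exact. With `target_dim=None` the step with maximal CV
accuracy wins, ties preferring the smaller set. If the filter retains
fewer than `target_dim` genes the floor clamps to d1.

## Consensus

Selections from repeated runs (varying only the fold-assignment seed) or
from different datasets are compared in all unordered pairs; every gene in
at least one pairwise intersection enters the biomarker module with a
support count equal to the number of pairs containing it. The minimum
support defaults to 1 pair and is configurable; no single threshold is
privileged, because published gene-set sizes depend on additional manual
curation that is out of scope here. Cross-dataset comparisons can
case-fold gene symbols first (`harmonize`); unmatched identifiers pass
through untouched.

## Evaluation

Confusion counts with ACC = (TP+TN)/(TP+TN+FP+FN), F1 = 2TP/(2TP+FP+FN),
PRE = TP/(TP+FP); precision is reported as null when nothing is predicted
positive, F1 likewise when its denominator vanishes. ROC curves sweep the
distinct scores in descending order ("positive if score ≥ threshold"),
tied scores collapse to a single threshold, the endpoints (0,0) and (1,1)
are always present, AUC is trapezoidal, and the Gini index is 2·AUC − 1 by
construction. The precision-recall area uses the step-wise
(average-precision) convention Σ Δrecall · precision. Sample distances are
plain Euclidean distances between sample columns, and heatmap ordering is
the leaf order of average-linkage hierarchical clustering on that matrix
(deterministic for a fixed input).

## Synthetic data

The generator emulates the shape of normalized, log2-scale two-class
expression matrices: every gene draws i.i.d. Gaussian noise around a
baseline (default mean 7.0, SD 1.0 on the log2 scale, mid-range for
normalized microarray intensities), and a planted subset of genes gains
`effect_size · noise_sd` in the cancer class. Default study conditions:
2000 genes, 30 + 30 samples, 20 informative genes, effect size 2.0 —
small-sample/high-dimension proportions at a size that keeps the full
pipeline fast at desk scale. A Student-t option (variance-matched,
df > 2) provides heavier-tailed noise for robustness checks.

What the generator does *not* emulate: gene–gene correlation, batch
effects, probe-level structure, intensity-dependent variance, or class
imbalance beyond what the per-class sample counts encode. Passing the
planted-recovery tests therefore demonstrates correctness of the selection
machinery under idealized independent noise, not performance on real
arrays, where correlated genes can substitute for one another and recovery
of a specific planted list is not the right target.

## Validation design

Every formula has an independent oracle in the test suite: a term-by-term
Fisher-score evaluation in plain Python, central-difference gradients for
the logistic cost, an exhaustive greedy backward-elimination oracle (same
importance rule, scipy BFGS optimizer rather than the package's gradient
descent) for pace-1 RFE, pair-counting for ROC AUC, and literal threshold
enumeration for the PR area. The RFE/oracle comparison uses l2 = 1.0 so
the optimum is unique and both optimizers converge to the same weights;
without a penalty, separable data has no finite optimum and the
elimination order is not a well-posed comparison. `scripts/acceptance.py`
re-runs these oracle comparisons and the planted-recovery study from
scratch at the default study conditions (20 replicates of the default
generator settings, target_dim 40 so that recovery is measured on a subset
twice the planted size).

## Numerical choices and limitations

* Population (biased) variance throughout the Fisher score; with both
  conventions applied consistently the ranking is unaffected for fixed
  class sizes.
* All tie-breaks (score ties, importance ties, CV-accuracy ties) are
  resolved lexicographically or toward the smaller subset, never randomly.
* The only random ingredients are the synthetic generator and the fold
  assignment, both driven by explicit integer seeds; two runs with the
  same seed are identical to the bit.
* Probe collapsing groups probes that differ only in a trailing
  ``.<number>`` suffix and represents each gene by the probe group with
  the largest grand mean. This grouping is a convention, not a claim
  about any particular array's probe-set semantics; supply a pre-collapsed
  matrix to bypass it.
* RFE cost grows linearly in the number of steps × folds; post-filter
  dimensionalities in the thousands with pace 2 are noticeably slower than
  the defaults, and `max_keep` exists partly to bound that cost.
* Multi-class inputs are accepted by the Fisher score itself, but the
  classifier, RFE, and all evaluation assume binary labels.
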