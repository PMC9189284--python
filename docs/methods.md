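# Methods

This note documents the statistical procedures implemented in `scmarkers`,
the defaults they ship with, the synthetic-data model used to exercise them,
and the numerical choices made where the design was genuinely open.

## Problem setting

The input is a labelled expression matrix: N cells × G genes of non-negative
TPM-like values, each cell carrying one of K cell-type labels.  Class sizes
are typically very unequal (the bundled study-shaped configuration spans a
12-fold imbalance across 16 classes, 1,147 cells).  The goal is a compact,
ordered set of marker genes, a cross-validated estimate of how well they
discriminate the classes, and quantitative threshold rules per cell type.
Values are consumed as provided; no normalization is applied.

## Stage 1 — all-relevant filtering with shadow variables

Per iteration: every live feature gets a *shadow* — an independent row
permutation of its column, which preserves the marginal distribution but
destroys any class association.  A 100-tree random forest (Gini impurity) is
fitted on [live ∪ shadow] columns and mean-impurity-decrease importances are
read off.  A live feature scores a hit when its importance **strictly**
exceeds the iteration's maximum shadow importance (ties count as no hit —
the conservative direction).  After each iteration every undecided feature's
hit count is tested two-sidedly against Binomial(iterations, ½), Bonferroni-
corrected across the currently undecided features; significant excess
confirms, significant deficit rejects and removes the feature (and its
shadow).  The loop stops when nothing is undecided or after `max_iter`
iterations (default 100; test level `alpha` default 0.05); leftovers are
*tentative* and excluded from the downstream matrix unless `keep_tentative`
is set.

Two properties worth knowing:

* Confirmed features stay in the model (with shadows) until the end, so the
  shadow pool shrinks as noise is rejected.
* The binomial null is approximate: the expression matrix is fixed across
  iterations, so a noise feature that happens to correlate with the labels
  *in this sample* beats the shadow maximum consistently.  The procedure
  therefore controls the per-feature false-confirmation **rate** (empirically
  ≈ alpha on pure noise) rather than guaranteeing zero false confirmations
  per run.  The test suite checks the rate.

## Stage 2 — mRMR ranking

Continuous expression is discretized per gene into three states by the
thresholds mean ± σ·sd (σ default 1; a constant gene maps to the single
middle state).  Mutual information is the plug-in estimate on the joint
empirical histogram, in nats.  The greedy ranking starts from the feature
with maximal relevance MI(f, c) and then repeatedly selects the unselected
feature maximizing φ = MI(f, c) − (1/|S|) Σ_{s∈S} MI(f, s) (the difference
form of the criterion; the quotient form is not implemented) until all
features are ranked.  Redundancy terms are accumulated incrementally — each
pairwise MI is computed exactly once — and a test asserts equality with a
from-scratch greedy recomputation.  Ties break toward the lower input column
index, making ranked lists reproducible.  `top=k` stops after the first k
selections (the greedy prefix is invariant to the stopping point), which is
how desk-scale IFS runs are kept affordable.

## Stage 3 — class balancing (SMOTE)

Minority classes are raised to the majority count by interpolation: pick a
random class member x, one of its k nearest same-class neighbours x_nn
(Euclidean distance on the features in play, k default 5, truncated to
class size − 1), and emit x + ζ(x_nn − x) with ζ ~ Uniform[0, 1].  Synthetic
values are convex combinations, so non-negativity is preserved.  Classes of
one cell are rejected (no neighbour exists).

Placement matters.  The default (`smote_mode="fold_internal"`) balances each
training fold separately inside cross-validation, so synthetic points are
never derived from held-out cells.  `"global"` balances once from the full
matrix before CV — test folds still contain only original cells, but
synthetic neighbours of test cells leak into training.  On a zero-effect
control this leakage alone inflates the apparent MCC to ≈ 0.5, which is why
fold-internal is the default; the global mode exists because balance-then-CV
is a common (if optimistic) protocol in the applied literature and allows
direct comparison with it.  Reported scores never include synthetic cells in
either mode.

## Stage 4 — incremental feature selection

Nested prefixes of the ranked list (lengths step, 2·step, …, always ending
at the full list; step default 1) are each scored by stratified k-fold CV
(default 10 folds).  Fold assignment is round-robin within class after a
seeded shuffle, so per-fold class imbalance is at most one cell and classes
smaller than the fold count degrade gracefully; one fold assignment is
shared by every prefix of a curve so that curve differences reflect
features, not fold noise.  Held-out predictions are pooled into a single
confusion table (micro evaluation) and summarized by:

* **multi-class MCC** (one-hot covariance form), range [−1, 1], returned as
  0 when truth or prediction is constant (the formula is undefined there and
  0 is its "no better than random" anchor);
* overall accuracy (confusion trace / total);
* per-class accuracy (diagonal / row sum, classes present in the truth).

Classifier families and their fixed settings: random forest (100 trees,
Gini), k-nearest-neighbour (K = 1, Minkowski exponent 2), decision tree
(CART, Gini, grown until pure).  No hyperparameter tuning is performed.
The *optimal* record maximizes MCC (ties → fewer features); the *compact*
record is the smallest prefix with MCC ≥ max − δ (δ default 0.01).

## Stage 5 — rule extraction

A CART/Gini tree is fitted on all original cells (synthetic cells are never
used here) over a chosen feature prefix and left unpruned.  Each leaf yields
one conjunctive rule: the root-to-leaf threshold conditions, merged per gene
to the tightest bounds (at most one ≤ and one > per gene; thresholds are
CART midpoints between adjacent observed values; ≤ goes left), predicting
the leaf majority class, annotated with leaf support and purity.  Because
leaves partition the feature space the rules are mutually exclusive and
exhaustive — `apply_rules` verifies that exactly one rule fires per cell and
raises otherwise — and every class present in training owns at least one
rule.

## Synthetic data model

The generator emulates the statistical shape the pipeline assumes, not any
particular sequencing chemistry.  Entry (cell of class c, gene g) is
exp(Normal(μ₀ + e·[g ∈ markers(c)], σ₀)), zeroed with probability d:
log-normal baseline (heavy-tailed, non-negative, TPM-like), a log-scale
marker shift e, and multiplicative dropout d mimicking single-cell sparsity.
Marker blocks are disjoint and deterministically assigned (the first
m·K gene columns, partitioned in class order) so recovery tests are
self-describing.  The study-shaped default is 16 classes with the published
sample sizes (96, 34, 15, 24, 68, 128, 59, 84, 177, 31, 75, 22, 32, 140,
67, 95; total 1,147), G = 500 genes, m = 5 markers/class, e = 2.5, μ₀ = 1,
σ₀ = 1, d = 0.3.  Not modelled: read counts/UMIs, library-size effects,
batch structure, correlated co-expression modules, or markers shared
between classes.  Passing tests on this fixture therefore demonstrate the
pipeline's mechanics and its ranking/recovery behaviour under clean
block-structured signal, not performance on real single-cell data.

One geometric consequence is worth flagging: disjoint log-normal marker
blocks make classes nearly linearly separated in Euclidean space, which is
close to ideal for 1-nearest-neighbour.  On this fixture 1-NN therefore
performs on par with — and often slightly above — the random forest, whereas
on real expression data (correlated genes, shared programs, label noise)
forests typically win.  Algorithm rankings observed on the fixture should be
read with that caveat.

## Desk-scale problem sizes

The bundled tests and the acceptance script run the method end to end at
reduced sizes chosen as a deliberate trade-off between fidelity and a
single-CPU desk run: the study-shaped fixture (1,147 × 500) for filtering
and recovery; mRMR ranking truncated to the top 64 features and IFS curves
on 2–4 prefix sizes (16–64 features) with 10-fold CV for the classifier
comparison; a 32-feature prefix for the zero-effect null control; 10,000
random cells for the rule-tiling check.  Full-scale runs (step 1 over
thousands of features) use exactly the same code paths via the CLI.

## Error handling and degenerate inputs

Matrices must be non-negative, finite, with unique ids and a label per cell;
violations raise typed errors naming offending cells.  Training operations
require ≥ 2 classes and ≥ 2 cells per class.  Constant features discretize
to a single state (MI 0) and sort to the bottom of the ranking; an empty
post-filter feature set raises rather than returning an empty matrix.
Classes absent from a training fold produce a warning, not an error.  All
stochastic stages take explicit seeds; the CLI derives per-stage seeds from
one master seed and records them in the run manifest.

## Known limitations

* Boruta importances are impurity-based (biased toward high-cardinality
  features in general; immaterial here because shadows share the feature's
  distribution) and the binomial decision rule is approximate as described.
* The plug-in MI estimator is biased upward for small samples; with three
  states and ≥ tens of cells the effect on the greedy order is negligible,
  but rankings of near-ties are not meaningful.
* The quotient mRMR variant, borderline-SMOTE/ADASYN, additional classifier
  families, nested CV and enrichment analysis are out of scope.
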