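# Methods

## The problem

A party who controls a labeled dataset before release can rewrite the
feature matrix so that any later cross-validated analysis finds inflated
classifier accuracy, while the released data remain nearly
indistinguishable from the originals. `enhancekit` implements two such
*enhancement attacks* for classification, together with the evaluation
harness an independent analyst would use, so that the attacks' behavior
can be studied quantitatively on synthetic cohorts.

The threat model is stronger than white-box adversarial attacks: the
attacker owns the entire dataset (training *and* test rows) and modifies
it once, before release. Labels are never touched; only `X` changes.

## Whole-dataset enhancement

The dataset `D = (X, y)` is split into `K` folds (stratified by class,
default `K = 5`). For each fold, the target classifier `f` is trained on
the in-fold rows, and each held-out row `x` is moved one step *down* the
per-sample input gradient `g = ∇ₓA` of an attacker objective `A`:

    x ← x − λ ĝ

where `ĝ` is the normalized gradient and `λ ≥ 0` is the enhancement
scale. After one pass every row has been moved exactly once. Because
models trained on overlapping in-fold sets are similar, all rows of a
class move in nearly the same direction, carving clean class structure
into the features that any re-trained classifier — including other model
families — will rediscover.

The attacker objective is either:

* **decision function** (binary/multiclass linear models): the true-class
  vs. strongest-rival margin. For a binary linear model with coefficients
  `w` this reproduces the closed-form update `x ← x ± ε w` (sign by
  class) exactly, and for `K > 2` classes it steps along
  `w_true − w_rival`, which collapses to the binary rule at `K = 2`.
* **loss** (all models): the per-sample training loss at the true label —
  multinomial cross-entropy for logistic regression and the net,
  margin/hinge loss for the SVM. Descending it pushes the sample toward
  confident correct classification.

**Normalization.** Each held-out row's gradient is scaled to unit norm
before the `λ` step (`per_sample`, the default), so every sample moves by
exactly `λ` per pass and `λ` is interpretable as a perturbation radius in
feature units. A `fold_block` variant (whole held-out gradient matrix to
Frobenius norm 1) is also provided; it divides the per-row step by
roughly the square root of the fold size, so the same nominal `λ` is
~7× weaker at `n = 245`, `K = 5`. All sweep scales quoted below are on
the per-sample convention.

**Schedules.** `post_pass` trains every fold's model on the *original*
data and commits all updates together after the loop — most effective for
linear models, whose coefficient direction is stable. `per_fold_iterative`
commits each fold immediately and applies the step in `n_inner_steps`
(default 10) sub-steps of `λ / n_inner_steps`, re-evaluating the fold
model's input gradient on the partially moved block between sub-steps —
more effective for the net, whose input gradients change as the block
moves. The package defaults to `per_fold_iterative` + loss for the net
and `post_pass` + decision function for SVM/LR.

The attack's fold plan is seeded independently of the evaluator's: the
victim re-partitions the released data with their own folds, and the
attack must survive that.

## Method-specific enhancement

Enhancement gradients transfer across model families, so the plain attack
inflates every model. To favor `f₁` over a rival `f₂`, both are trained
per fold and each held-out row is updated with mutually orthogonalized
gradients:

    g₁′ = proj_{g₂⊥}(g₁)        g₂′ = proj_{g₁⊥}(g₂)
    x  ← x − λ (g₁′ − η g₂′)

`g₁′` carries `f₁`'s improvement direction stripped of its component
along `f₂`'s gradient (no first-order transfer), and the `+λη g₂′` term
*ascends* `f₂`'s loss in a direction orthogonal to `g₁`, actively holding
`f₂` back after it retrains; `η ≥ 0` is the suppression coefficient. The
combined step is normalized per sample before scaling by `λ`. Projections
are row-wise (the update is defined per held-out sample); rows where both
gradients vanish are left unchanged. Fold updates are committed
immediately, one pass, 10 folds by default. `f₂`'s gradient always uses
the loss objective (the decision-function objective is binary-linear
only).

Observed behavior on the synthetic cohort: the widest `f₁ − f₂` accuracy
gap occurs at the largest `λ` with *small* `η` — the suppression term
trades away some of `f₁`'s own gain while pushing `f₂` down, so raising
`η` lowers `f₂`'s accuracy (its intended effect) but does not widen the
gap monotonically.

## Classifier adapters

All adapters implement one contract: `fit`, `predict` (score ties break
to the lowest class index), and `input_gradient` returning one gradient
row per input row.

* **Linear SVM** — scikit-learn `LinearSVC` (L2, hinge-type, one-vs-rest
  for `K > 2`), `C = 1` during attacks. Input gradients are closed-form
  in the fitted coefficients.
* **Logistic regression** — scikit-learn `LogisticRegression`
  (multinomial, L2, `C = 1` during attacks); closed-form gradients
  `Σₖ (pₖ − [k = y]) wₖ`.
* **Feedforward net** — three fully connected layers with ReLU
  activations (hidden widths 64 and 32 by default), softmax
  cross-entropy, Adam (`α = 10⁻³`, batch 10, 10 epochs), implemented
  directly in numpy with exact backpropagation so per-sample input
  gradients are analytic. Weight init and batch order are keyed to a
  single seed; fits are bit-reproducible. Verified against central finite
  differences to ~1e-10 relative error.

Hyperparameters are frozen during attacks; the attack never tunes the
model it differentiates.

## Evaluation harness

`nested_cv_evaluate` is the victim's-eye view: outer `K`-fold accuracy
(5 folds for the whole-dataset experiments, 10 for the selective ones)
where each outer fold's `C ∈ {10⁻⁴, 10⁻³, 10⁻², 10⁻¹, 1}` is chosen by
3-fold inner grid search on the outer-training data only (ties go to the
smallest `C`, for determinism). The net uses its fixed recipe — no grid.
Accuracy is plain proportion correct; balanced accuracy is carried as an
auxiliary column. Outer folds are stratified and re-drawn per repetition
seed. The evaluator never mutates its input and never sees the attack's
fold plan.

`transferability_matrix` crafts an enhanced dataset with each attacker
model and evaluates every victim model on it; `run_sweep` produces tidy
(λ, η, model, seed) → (accuracy, similarity r) tables.

Similarity auditing (`feature_similarity`) reports the Pearson
correlation of the original and enhanced matrices flattened entry-wise —
the headline stealth number — plus per-row correlations and the largest
absolute per-entry change. The flattened-global convention is the
default; per-sample values are available because the granularity is a
reporting choice.

## Synthetic cohorts

The generator emulates a case-control functional-connectome study
without any imaging: four diagnostic classes of sizes 117/46/44/38
(n = 245, modal-class chance level 47.76%) and 2,000 features standing in
for Fisher-z connectivity edges. Each feature has a subject-independent
baseline drawn from N(0.25, 0.25²) — the spread of edge means across a
connectome — and subjects scatter around their class mean with
within-class sd 0.1 per feature, matching the ≈1/√(T−3) sampling noise of
a Fisher-z estimate at typical fMRI run lengths. Class means sit at
mutual distance `separation × within-class sd` along random orthonormal
directions, so the class signal is distributed across many features and
no single edge is diagnostic.

2,000 features (not a full 268-node connectome's 35,778) keep the full
experiment suite at desk scale; the attacks' geometry — a per-sample step
of norm `λ` against within-class noise of sd 0.1 per direction — does not
depend on the ambient dimension, only on this ratio.

`calibrate_separation` bisects the separation until a chosen model's
nested-CV accuracy hits a target (the shipped preset is calibrated to a
~50% logistic-regression baseline, i.e. near chance; the bisection is
re-run from scratch by `scripts/acceptance.py`). A `connectome_mode`
instead emits per-subject node time series whose class-dependent
correlation structure induces approximately the same standardized
separation after the Pearson → Fisher-z → upper-triangle pipeline
(class edge profiles are offset by `separation/√(T−3)` in z-space, the
per-subject estimation noise), exercising the feature-construction code
path end to end.

What the generator does *not* model: spatial/topological structure of
real connectomes, site and motion confounds, heavy-tailed edge noise, and
label noise. Passing results show the attacks behave as designed under
the intended signal-to-noise regime; absolute accuracies on real imaging
cohorts will differ.

## Numerical choices and edge cases

* Correlations are clipped to ±0.999999 before `atanh`, keeping Fisher-z
  features finite for perfectly correlated series; connectome diagonals
  are forced to 0, never `atanh(1)`.
* Upper-triangle vectorization is strictly row-major above the diagonal
  and round-trips exactly with its inverse.
* Zero gradients: a zero row (or zero block) passes through normalization
  unchanged, so degenerate samples are left where they are — including
  rows whose two gradients are parallel in the selective attack (their
  orthogonal component vanishes by construction).
* Projection onto the complement of a zero vector returns the input
  unchanged.
* Stratified fold plans degrade to plain shuffled K-fold (with a warning)
  when the smallest class has fewer members than folds.
* `λ = 0` is a bitwise identity for both attacks.
* All randomness flows from explicit integer seeds through
  `SeedSequence`-derived sub-seeds (attack folds, per-fold model fits,
  evaluator folds are independent streams).

## Problem sizes used in the shipped experiments

Tests and the acceptance script run the full n = 245 × 2,000 cohort for
the headline sweeps (scale grid {0, 0.5, 1, 2, 4} for the whole-dataset
attack; {0.1, 0.2, 0.4, 0.8} × η ∈ {0, 0.5, 1} for the selective attack)
and a 84 × 300 analogue for property checks that need many repeated
attack/evaluate cycles, such as the 5-seed suppression-monotonicity
check.

## Known limitations

* Only one rival model can be suppressed at a time; the construction does
  not extend to suppressing several models simultaneously.
* The decision-function objective is implemented for linear models only;
  the net attacks through its loss.
* Graph-structured deep models (e.g. convolutional networks over
  connectivity matrices) satisfy the adapter contract but no adapter is
  shipped.
* The harness evaluates attacks on already-constructed feature matrices;
  perturbing upstream raw data (e.g. time series before correlation) is
  out of scope.
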