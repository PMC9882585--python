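# enhancekit

Gradient-based **enhancement attacks** on cross-validated classifiers:
tooling to study how a party who controls a labeled dataset can rewrite
its feature matrix — before release — so that any later cross-validated
analysis finds falsely inflated accuracy, while the released features
remain nearly identical to the originals (Pearson r > 0.99). The package
is aimed at researchers studying the trustworthiness of machine-learning
results on shared biomedical data (the motivating setting is functional
connectome classification), and at anyone building defenses or audits
against such manipulation.

## What it implements

**Whole-dataset enhancement.** Split `D = (X, y)` into K folds; for each
fold, train the target classifier `f` on the in-fold rows and move every
held-out row down the per-sample input gradient of an attacker objective
`A` (the per-sample loss `L`, or the decision-function margin `DF` for
linear models):

    g = ∇ₓA,    x ← x − λ ĝ

with `ĝ` the unit-norm gradient direction and `λ` the enhancement scale.
One pass updates every sample exactly once. For a binary linear model
with coefficients `w` this is exactly `x ← x ± ε w` (sign by class) —
every sample is pushed toward its own side of the boundary, so a
re-trained classifier on fresh folds finds near-perfect structure.

**Method-specific enhancement.** To favor model `f₁` over a rival `f₂`
(whose gradients would otherwise transfer), the update uses mutually
orthogonalized gradients with a suppression coefficient `η`:

    g₁′ = proj_{g₂⊥}(g₁),   g₂′ = proj_{g₁⊥}(g₂)
    x ← x − λ (g₁′ − η g₂′)

**Harness.** Classifier adapters (linear SVM, logistic regression, and a
3-layer ReLU feedforward net with exact analytic input gradients) behind
one fit/predict/input-gradient contract; nested cross-validated
evaluation with per-fold grid search over the L2 strength
`C ∈ {1e-4 … 1}`; attack-transferability matrices; λ/η sweeps;
original-vs-enhanced similarity auditing; connectome feature construction
(Pearson correlation → Fisher z → upper-triangle vectorization); and a
synthetic cohort generator emulating an imbalanced 4-class,
high-dimensional, near-chance-separable case-control study
(class sizes 117/46/44/38, chance level 47.76%).

See `docs/methods.md` for the model, parameter and design details.

## Worked example

```python
from enhancekit import (cnp_like_spec, generate_cohort, chance_level,
                        default_config_for, enhance_dataset, nested_cv_evaluate)

cohort = generate_cohort(cnp_like_spec(n_features=2000, seed=0))
print(f"n={cohort.n_samples}, p={cohort.n_features}, chance={chance_level(cohort.y):.4f}")

baseline = nested_cv_evaluate(cohort, "logreg", n_folds=5, seeds=(0,))
print(f"baseline accuracy: {baseline.accuracy_mean:.4f}")

cfg = default_config_for("logreg", lambda_scale=2.0, n_folds=5, seed=0)
attacked = enhance_dataset(cohort, "logreg", cfg)
enhanced = nested_cv_evaluate(attacked.enhanced, "logreg", n_folds=5, seeds=(0,))
print(f"enhanced accuracy: {enhanced.accuracy_mean:.4f}")
print(f"similarity r: {attacked.similarity.r:.4f}, "
      f"max |dX|: {attacked.similarity.max_abs_change:.4f}")
```

prints

```
n=245, p=2000, chance=0.4776
baseline accuracy: 0.4857
enhanced accuracy: 1.0000
similarity r: 0.9865, max |dX|: 0.1776
```

The cohort is genuinely near chance (48.6% vs. 47.8% majority class), yet
after one enhancement pass at `λ = 2` an independent nested-CV analysis
of the rewritten features reports 100% accuracy — while the enhanced
matrix correlates with the original at r = 0.99 and no single entry moved
by more than 0.18 (feature values span roughly −0.5 … 1.0).

The same workflow is available from the shell:

```sh
enhancekit simulate --preset cnp-like --seed 0 --out-features F.csv --out-labels y.csv
enhancekit enhance  --features F.csv --labels y.csv --model logreg --lambda 2.0 \
                    --out F_enh.csv --report report.json
enhancekit evaluate --features F_enh.csv --labels y.csv --model logreg --seeds 10
enhancekit sweep    --features F.csv --labels y.csv --attack method_enhance \
                    --lambdas 0.1,0.2,0.4,0.8 --etas 0,0.5,1 --out sweep.csv
enhancekit transfer --features F.csv --labels y.csv --lambda 2.0 --out transfer.csv
```

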