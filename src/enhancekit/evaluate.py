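"""The victim's-eye view: nested cross-validated accuracy, transferability
matrices, and lambda/eta sweep experiments.

Evaluation deliberately knows nothing about the attack: it re-partitions
the (possibly enhanced) dataset with its own seed-derived folds, selects
the L2 strength ``C`` for the linear models by inner-fold grid search on
the outer-training data only, and reports plain proportion-correct
accuracy (balanced accuracy is carried along as an auxiliary column).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score

from .data import Dataset, derive_seed, make_fold_plan
from .enhance import EnhancementConfig, default_config_for, enhance_dataset
from .method_enhance import MethodEnhancementConfig, method_enhance_dataset
from .models import make_model, model_tag

__all__ = [
    "DEFAULT_C_GRID",
    "EvaluationReport",
    "TransferMatrix",
    "nested_cv_evaluate",
    "transferability_matrix",
    "run_sweep",
]

#: L2 strengths searched for the linear models within each outer fold
DEFAULT_C_GRID = (1e-4, 1e-3, 1e-2, 1e-1, 1.0)


@dataclass
class EvaluationReport:
    model_tag: str
    accuracy_mean: float
    accuracy_sd: float
    per_fold_accuracies: list[float]
    chosen_params: list[dict]
    n_folds: int
    seeds: tuple[int, ...]
    balanced_accuracy_mean: float = float("nan")

    def __post_init__(self) -> None:
        for a in self.per_fold_accuracies:
            if not 0.0 <= a <= 1.0:
                raise ValueError("accuracies must lie in [0, 1]")


@dataclass
class TransferMatrix:
    """Rows: model used to craft the attack; columns: model evaluated."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.table.to_numpy(dtype=float)
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("transfer accuracies must lie in [0, 1]")


def _inner_select_C(Xtr, ytr, model_spec, grid, inner_folds, stratified, seed) -> float:
    """Smallest C attaining the best mean inner-fold accuracy."""
    plan = make_fold_plan(ytr, inner_folds, stratified, seed)
    best_C, best_acc = None, -np.inf
    for C in sorted(grid):
        accs = []
        for itr, iho in plan:
            m = make_model(model_spec, seed=seed, C=C)
            m.fit(Xtr[itr], ytr[itr])
            accs.append(float(np.mean(m.predict(Xtr[iho]) == ytr[iho])))
        mean_acc = float(np.mean(accs))
        if mean_acc > best_acc:  # strict: ties keep the smaller C
            best_C, best_acc = C, mean_acc
    return best_C


def nested_cv_evaluate(
    dataset: Dataset,
    model_spec,
    grid=DEFAULT_C_GRID,
    n_folds: int = 5,
    seeds=(0,),
    inner_folds: int = 3,
    stratified: bool = True,
) -> EvaluationReport:
    """Outer-K-fold accuracy with per-fold inner grid search.

    Each outer fold's hyperparameters are chosen by ``inner_folds``-fold
    grid search on the outer-training data only; the whole procedure is
    repeated for every seed (fresh partitions each time) and all per-fold
    accuracies are pooled.  The net takes no grid (its hyperparameters are
    fixed); supplying one triggers a warning and is ignored.
    """
    tag = model_tag(model_spec)
    probe = make_model(model_spec)
    if grid is not None and len(grid) > 0 and not probe.supports_C_grid:
        warnings.warn(f"model '{tag}' takes no C grid; ignoring it", stacklevel=2)
        grid = None
    use_grid = grid is not None and len(grid) > 0 and probe.supports_C_grid
    X, y = dataset.X, dataset.y
    per_fold, chosen, balanced = [], [], []
    seeds = tuple(int(s) for s in seeds)
    for s in seeds:
        plan = make_fold_plan(y, n_folds, stratified, seed=derive_seed(s, 101))
        for k, (tr, ho) in enumerate(plan):
            fit_seed = derive_seed(s, 7, k)
            if use_grid:
                C = _inner_select_C(
                    X[tr], y[tr], model_spec, grid, inner_folds, stratified,
                    seed=derive_seed(s, 11, k),
                )
                model = make_model(model_spec, seed=fit_seed, C=C)
                chosen.append({"seed": s, "fold": k, "C": C})
            else:
                model = make_model(model_spec, seed=fit_seed)
                chosen.append({"seed": s, "fold": k})
            model.fit(X[tr], y[tr])
            pred = model.predict(X[ho])
            per_fold.append(float(np.mean(pred == y[ho])))
            balanced.append(float(balanced_accuracy_score(y[ho], pred)))
    n_per_seed = len(per_fold) // len(seeds)
    seed_means = [
        float(np.mean(per_fold[i * n_per_seed : (i + 1) * n_per_seed]))
        for i in range(len(seeds))
    ]
    sd = float(np.std(seed_means, ddof=1)) if len(seeds) > 1 else 0.0
    return EvaluationReport(
        model_tag=tag,
        accuracy_mean=float(np.mean(per_fold)),
        accuracy_sd=sd,
        per_fold_accuracies=per_fold,
        chosen_params=chosen,
        n_folds=n_folds,
        seeds=seeds,
        balanced_accuracy_mean=float(np.mean(balanced)),
    )


def transferability_matrix(
    dataset: Dataset,
    attacker_specs,
    victim_specs,
    lambda_scale: float,
    attack_seed: int = 0,
    attack_folds: int = 5,
    grid=DEFAULT_C_GRID,
    n_folds: int = 5,
    seeds=(0,),
    inner_folds: int = 3,
) -> TransferMatrix:
    """Enhance with each attacker model, evaluate every victim model on the
    enhanced dataset; entry [attacker, victim] is the victim's nested-CV
    accuracy."""
    rows = {}
    for atk in attacker_specs:
        cfg = default_config_for(atk, lambda_scale=lambda_scale,
                                 n_folds=attack_folds, seed=attack_seed)
        enhanced = enhance_dataset(dataset, atk, cfg).enhanced
        row = {}
        for victim in victim_specs:
            rep = nested_cv_evaluate(
                enhanced, victim,
                grid=grid if make_model(victim).supports_C_grid else None,
                n_folds=n_folds, seeds=seeds, inner_folds=inner_folds,
            )
            row[model_tag(victim)] = rep.accuracy_mean
        rows[model_tag(atk)] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "attacker"
    table.columns.name = "victim"
    return TransferMatrix(table=table)


def run_sweep(
    dataset: Dataset,
    attack_kind: str,
    lambda_grid,
    eta_grid=(0.0,),
    seeds=(0,),
    out_path=None,
    model_specs=("svm", "logreg", "fnn"),
    f1_spec="fnn",
    f2_spec="logreg",
    attack_folds: int | None = None,
    eval_folds: int | None = None,
    grid=DEFAULT_C_GRID,
    inner_folds: int = 3,
) -> pd.DataFrame:
    """Tidy sweep table: one row per (lambda, eta, model, seed) with the
    model's nested-CV accuracy on the attacked dataset and the similarity
    ``r`` of the attacked features to the originals.

    ``attack_kind`` is ``"enhance"`` (whole-dataset attack; ``eta_grid``
    ignored, one row per attacked model) or ``"method_enhance"``
    (selective attack on ``f1_spec`` vs ``f2_spec``; two rows per setting,
    one per model).
    """
    if attack_kind not in ("enhance", "method_enhance"):
        raise ValueError("attack_kind must be 'enhance' or 'method_enhance'")
    if len(tuple(lambda_grid)) == 0:
        raise ValueError("lambda_grid must be non-empty")
    records = []
    if attack_kind == "enhance":
        attack_folds = 5 if attack_folds is None else attack_folds
        eval_folds = 5 if eval_folds is None else eval_folds
        for spec in model_specs:
            for lam in lambda_grid:
                for s in seeds:
                    cfg = default_config_for(spec, lambda_scale=float(lam),
                                             n_folds=attack_folds, seed=int(s))
                    res = enhance_dataset(dataset, spec, cfg)
                    rep = nested_cv_evaluate(
                        res.enhanced, spec,
                        grid=grid if make_model(spec).supports_C_grid else None,
                        n_folds=eval_folds, seeds=(int(s),), inner_folds=inner_folds,
                    )
                    records.append(dict(
                        attack="enhance", model=model_tag(spec), lam=float(lam),
                        eta=0.0, seed=int(s), accuracy=rep.accuracy_mean,
                        balanced_accuracy=rep.balanced_accuracy_mean,
                        similarity_r=res.similarity.r,
                    ))
    else:
        attack_folds = 10 if attack_folds is None else attack_folds
        eval_folds = 10 if eval_folds is None else eval_folds
        if len(tuple(eta_grid)) == 0:
            raise ValueError("eta_grid must be non-empty")
        for lam in lambda_grid:
            for eta in eta_grid:
                for s in seeds:
                    cfg = MethodEnhancementConfig(
                        f1_spec=f1_spec, f2_spec=f2_spec,
                        lambda_scale=float(lam), suppression=float(eta),
                        n_folds=attack_folds, seed=int(s),
                    )
                    res = method_enhance_dataset(dataset, cfg)
                    for spec in (f1_spec, f2_spec):
                        rep = nested_cv_evaluate(
                            res.enhanced, spec,
                            grid=grid if make_model(spec).supports_C_grid else None,
                            n_folds=eval_folds, seeds=(int(s),), inner_folds=inner_folds,
                        )
                        records.append(dict(
                            attack="method_enhance", model=model_tag(spec),
                            lam=float(lam), eta=float(eta), seed=int(s),
                            accuracy=rep.accuracy_mean,
                            balanced_accuracy=rep.balanced_accuracy_mean,
                            similarity_r=res.similarity.r,
                        ))
    df = pd.DataFrame.from_records(records)
    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_path, index=False)
    return df
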