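"""Method-specific enhancement via orthogonal gradient projections (goal #2).

Plain enhancement gradients transfer well between model families, so an
attack crafted for one classifier also inflates its rivals.  To enhance
model ``f1`` while holding back model ``f2``, each held-out sample is moved
along the component of ``f1``'s input gradient that is orthogonal to
``f2``'s (so the move carries no first-order signal for ``f2``), minus
``eta`` times the mirrored component of ``f2``'s gradient orthogonal to
``f1``'s (actively raising ``f2``'s loss without disturbing ``f1``):

    x  <-  x - lambda * ( proj_{g2-perp}(g1) - eta * proj_{g1-perp}(g2) )

where ``eta >= 0`` is the suppression coefficient.  As with the plain
attack, the combined step is normalized (each row to unit norm by default)
before scaling by ``lambda``, and labels are never touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Dataset, derive_seed, feature_similarity, make_fold_plan
from .enhance import NORMALIZATIONS, EnhancementResult, _step_delta
from .models import make_model, model_tag

__all__ = [
    "MethodEnhancementConfig",
    "orthogonal_component",
    "project_rows_orthogonal",
    "combined_step",
    "method_enhance_dataset",
]


@dataclass
class MethodEnhancementConfig:
    """Knobs of the selective (one-model-over-another) enhancement attack."""

    f1_spec: object = "fnn"
    f2_spec: object = "logreg"
    lambda_scale: float = 0.4
    suppression: float = 0.5
    n_folds: int = 10
    objective: str = "loss"
    normalization: str = "per_sample"
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_scale < 0:
            raise ValueError("lambda_scale must be >= 0")
        if self.suppression < 0:
            raise ValueError("suppression coefficient must be >= 0")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"normalization must be one of {NORMALIZATIONS}")
        if model_tag(self.f1_spec) == model_tag(self.f2_spec):
            raise ValueError("f1_spec and f2_spec must name different models")


def orthogonal_component(g1, g2) -> np.ndarray:
    """Component of ``g1`` orthogonal to ``g2``:
    ``g1 - (<g1,g2>/<g2,g2>) g2``; if ``g2`` is the zero vector, ``g1`` is
    returned unchanged."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape or g1.ndim != 1:
        raise ValueError(f"gradient rows must be 1-D and equal length, got {g1.shape} vs {g2.shape}")
    denom = float(g2 @ g2)
    if denom == 0.0:
        return g1.copy()
    return g1 - (float(g1 @ g2) / denom) * g2


def project_rows_orthogonal(G1: np.ndarray, G2: np.ndarray) -> np.ndarray:
    """Row-wise :func:`orthogonal_component` for whole gradient blocks."""
    G1 = np.asarray(G1, dtype=float)
    G2 = np.asarray(G2, dtype=float)
    if G1.shape != G2.shape:
        raise ValueError("gradient blocks must share a shape")
    denom = np.einsum("ij,ij->i", G2, G2)
    coef = np.where(denom == 0, 0.0, np.einsum("ij,ij->i", G1, G2) / np.where(denom == 0, 1.0, denom))
    return G1 - coef[:, None] * G2


def combined_step(G1: np.ndarray, G2: np.ndarray, eta: float) -> np.ndarray:
    """Raw (un-normalized) selective-enhancement direction
    ``proj_{g2-perp}(g1) - eta * proj_{g1-perp}(g2)``, row-wise."""
    return project_rows_orthogonal(G1, G2) - eta * project_rows_orthogonal(G2, G1)


def method_enhance_dataset(dataset: Dataset, config: MethodEnhancementConfig) -> EnhancementResult:
    """One fold-wise pass of the selective enhancement attack.

    Fold updates are committed immediately (training folds later in the
    pass see earlier enhanced blocks), mirroring how the plain attack's
    iterative schedule walks the partition.  Rows where both gradients
    vanish are left unchanged.
    """
    f2_objective = "loss"  # decision-function gradients are binary-linear only
    X_orig = dataset.X
    X_work = X_orig.copy()
    plan = make_fold_plan(dataset.y, config.n_folds, config.stratified, config.seed)
    per_fold_norms: list[float] = []
    for k, (tr, ho) in enumerate(plan):
        f1 = make_model(config.f1_spec, seed=derive_seed(config.seed, k, 1))
        f2 = make_model(config.f2_spec, seed=derive_seed(config.seed, k, 2))
        f1.fit(X_work[tr], dataset.y[tr])
        f2.fit(X_work[tr], dataset.y[tr])
        G1 = f1.input_gradient(X_work[ho], dataset.y[ho], config.objective).G
        G2 = f2.input_gradient(X_work[ho], dataset.y[ho], f2_objective).G
        C = combined_step(G1, G2, config.suppression)
        delta = _step_delta(C, config.lambda_scale, config.normalization)
        X_work[ho] = X_work[ho] - delta
        per_fold_norms.append(float(np.linalg.norm(delta)))
    enhanced = dataset.with_X(X_work)
    return EnhancementResult(
        enhanced=enhanced,
        per_fold_gradient_norms=per_fold_norms,
        config=config,
        similarity=feature_similarity(X_orig, X_work),
        model_tag=f"{model_tag(config.f1_spec)}-over-{model_tag(config.f2_spec)}",
    )
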