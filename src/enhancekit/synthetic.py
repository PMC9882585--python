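"""Synthetic cohorts with the statistical structure of a multi-site
case-control connectome study: several imbalanced diagnostic classes,
thousands of weakly informative features, and near-chance baseline
separability.

Features emulate Fisher-z functional-connectivity edges.  Each feature has
a subject-independent baseline level (edge means spread across the
connectome), and subjects scatter around their class mean with a
within-class standard deviation matching the sampling noise of a Fisher-z
correlation estimate at typical fMRI run lengths (roughly ``1/sqrt(T-3)``,
i.e. ~0.1).  Class means sit at mutual distance ``separation * within_sd``
along random orthonormal directions, so no single feature is diagnostic on
its own — the class signal is distributed, as in real connectome data.

``connectome_mode`` instead emits per-subject node time series whose
class-dependent correlation structure induces approximately the same
standardized separation once the connectome pipeline (Pearson + Fisher z +
upper-triangle vectorization) is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .data import Dataset, build_connectome, chance_level, devectorize_upper, vectorize_upper
from .evaluate import DEFAULT_C_GRID, nested_cv_evaluate

__all__ = [
    "SyntheticSpec",
    "CalibrationResult",
    "generate_cohort",
    "calibrate_separation",
    "cnp_like_spec",
    "load_preset",
    "spec_from_yaml",
    "spec_to_yaml",
]

#: default class sizes of the emulated cohort (modal class proportion 47.76%)
DEFAULT_CLASS_SIZES = (117, 46, 44, 38)


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic cohort; identical spec + seed is bitwise
    reproducible."""

    class_sizes: tuple[int, ...] = DEFAULT_CLASS_SIZES
    n_features: int = 2000
    separation: float = 1.0
    covariance: str = "isotropic"  # or "correlated_blocks"
    connectome_mode: bool = False
    n_nodes: int = 16
    n_timepoints: int = 150
    within_sd: float = 0.1
    edge_mean: float = 0.25
    edge_sd: float = 0.25
    block_size: int = 50
    block_rho: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_sizes = tuple(int(c) for c in self.class_sizes)
        if len(self.class_sizes) < 2 or any(c < 1 for c in self.class_sizes):
            raise ValueError("need >= 2 classes with >= 1 member each")
        if self.n_features < 2:
            raise ValueError("n_features must be >= 2")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.covariance not in ("isotropic", "correlated_blocks"):
            raise ValueError("covariance must be 'isotropic' or 'correlated_blocks'")
        if self.connectome_mode:
            if self.n_nodes < 2 or self.n_timepoints < 3:
                raise ValueError("connectome mode needs >= 2 nodes and >= 3 time points")
        if self.within_sd <= 0:
            raise ValueError("within_sd must be positive")
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must lie in [0, 1)")


@dataclass
class CalibrationResult:
    separation: float
    achieved_accuracy: float
    trace: list[tuple[float, float]] = field(default_factory=list)


def _orthonormal_directions(rng: np.random.Generator, dim: int, k: int) -> np.ndarray:
    """k orthonormal directions in R^dim (columns)."""
    Q, _ = np.linalg.qr(rng.standard_normal((dim, k)))
    return Q[:, :k]


def _class_means(rng, dim: int, K: int, baseline: np.ndarray, spacing: float) -> np.ndarray:
    """Class means at mutual Euclidean distance ``spacing`` around a
    baseline profile (orthonormal directions are sqrt(2) apart)."""
    U = _orthonormal_directions(rng, dim, K)
    return baseline[None, :] + (spacing / np.sqrt(2.0)) * U.T


def _nearest_correlation(R: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped positive-definite repair with unit diagonal."""
    R = (R + R.T) / 2.0
    vals, vecs = np.linalg.eigh(R)
    vals = np.clip(vals, floor, None)
    R = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


def _generate_tabular(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    p = spec.n_features
    K = len(spec.class_sizes)
    baseline = rng.normal(spec.edge_mean, spec.edge_sd, size=p)
    means = _class_means(rng, p, K, baseline, spec.separation * spec.within_sd)
    rows = []
    for k, size in enumerate(spec.class_sizes):
        if spec.covariance == "isotropic":
            noise = rng.standard_normal((size, p))
        else:
            noise = np.empty((size, p))
            for start in range(0, p, spec.block_size):
                stop = min(start + spec.block_size, p)
                shared = rng.standard_normal((size, 1))
                own = rng.standard_normal((size, stop - start))
                noise[:, start:stop] = (
                    np.sqrt(spec.block_rho) * shared + np.sqrt(1 - spec.block_rho) * own
                )
        rows.append(means[k] + spec.within_sd * noise)
    return np.vstack(rows)


def _generate_connectome(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    N, T = spec.n_nodes, spec.n_timepoints
    E = N * (N - 1) // 2
    K = len(spec.class_sizes)
    sigma_z = 1.0 / np.sqrt(T - 3)  # Fisher-z sampling sd of one edge estimate
    # baseline edge profile kept moderate so tanh stays well-conditioned
    z_base = rng.normal(spec.edge_mean, min(spec.edge_sd, 0.15), size=E)
    z_means = _class_means(rng, E, K, z_base, spec.separation * sigma_z)
    X = np.empty((sum(spec.class_sizes), E))
    row = 0
    for k, size in enumerate(spec.class_sizes):
        R = devectorize_upper(np.tanh(z_means[k]))
        np.fill_diagonal(R, 1.0)
        R = _nearest_correlation(R)
        L = np.linalg.cholesky(R)
        for _ in range(size):
            ts = rng.standard_normal((T, N)) @ L.T
            X[row] = vectorize_upper(build_connectome(ts))
            row += 1
    return X


def generate_cohort(spec: SyntheticSpec) -> Dataset:
    """Draw one cohort from the spec; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    X = _generate_connectome(spec, rng) if spec.connectome_mode else _generate_tabular(spec, rng)
    y = np.concatenate([np.full(size, k, dtype=int) for k, size in enumerate(spec.class_sizes)])
    return Dataset(X=X, y=y)


def calibrate_separation(
    spec: SyntheticSpec,
    target_accuracy: float,
    tolerance: float = 0.02,
    model_spec="logreg",
    n_folds: int = 5,
    inner_folds: int = 3,
    grid=DEFAULT_C_GRID,
    max_iter: int = 10,
    eval_seed: int = 0,
) -> CalibrationResult:
    """Bisection on ``separation`` until the nested-CV accuracy of
    ``model_spec`` on a fresh cohort is within ``tolerance`` of
    ``target_accuracy``.

    Returns the calibrated separation, the achieved accuracy, and the
    bisection trace of (separation, accuracy) pairs.  Raises if the upper
    bracket cannot be established within ``max_iter`` doublings.
    """
    y = np.concatenate([np.full(c, k) for k, c in enumerate(spec.class_sizes)])
    chance = chance_level(y)
    # target == chance is the separation -> 0 limit and is allowed
    if not chance <= target_accuracy < 1.0:
        raise ValueError(f"target accuracy must lie in [chance={chance:.4f}, 1)")

    trace: list[tuple[float, float]] = []

    def acc_at(sep: float) -> float:
        cohort = generate_cohort(replace(spec, separation=float(sep)))
        rep = nested_cv_evaluate(
            cohort, model_spec, grid=grid, n_folds=n_folds,
            seeds=(eval_seed,), inner_folds=inner_folds,
        )
        trace.append((float(sep), rep.accuracy_mean))
        return rep.accuracy_mean

    lo, hi = 0.0, max(spec.separation, 1.0)
    acc_lo = acc_at(lo)
    if abs(acc_lo - target_accuracy) <= tolerance:
        return CalibrationResult(lo, acc_lo, trace)
    acc_hi = acc_at(hi)
    expansions = 0
    while acc_hi < target_accuracy:
        hi *= 2.0
        expansions += 1
        if expansions > max_iter:
            best = min(trace, key=lambda t: abs(t[1] - target_accuracy))
            raise RuntimeError(
                f"could not bracket target {target_accuracy}; best found: "
                f"separation={best[0]:.4g} with accuracy={best[1]:.4f}"
            )
        acc_hi = acc_at(hi)
    best_sep, best_acc = min(trace[1:], key=lambda t: abs(t[1] - target_accuracy))
    for _ in range(max_iter):
        if abs(best_acc - target_accuracy) <= tolerance:
            break
        mid = (lo + hi) / 2.0
        acc_mid = acc_at(mid)
        if abs(acc_mid - target_accuracy) < abs(best_acc - target_accuracy):
            best_sep, best_acc = mid, acc_mid
        if acc_mid < target_accuracy:
            lo = mid
        else:
            hi = mid
    return CalibrationResult(float(best_sep), float(best_acc), trace)


# ---------------------------------------------------------------------------
# Presets (YAML-backed)


def load_preset(name: str) -> SyntheticSpec:
    """Load a named preset from the packaged presets file."""
    text = resources.files("enhancekit").joinpath("presets.yaml").read_text()
    presets = yaml.safe_load(text)
    if name not in presets:
        raise KeyError(f"unknown preset '{name}'; available: {sorted(presets)}")
    return SyntheticSpec(**presets[name])


def cnp_like_spec(n_features: int = 2000, seed: int = 0, **overrides) -> SyntheticSpec:
    """The default cohort: 117/46/44/38 class sizes, high-dimensional
    edge-like features, separation pre-calibrated to a near-chance
    (~50%) logistic-regression baseline."""
    spec = load_preset("cnp-like")
    return replace(spec, n_features=n_features, seed=seed, **overrides)


def spec_from_yaml(path) -> SyntheticSpec:
    with open(path) as fh:
        return SyntheticSpec(**yaml.safe_load(fh))


def spec_to_yaml(spec: SyntheticSpec, path) -> None:
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(spec).items()}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
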