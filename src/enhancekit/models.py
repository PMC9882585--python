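"""Classifier adapters exposing fit, predict, and per-sample input gradients.

Every adapter implements the :class:`GradientClassifier` contract: after
fitting, ``input_gradient(X, y, objective)`` returns one gradient row per
input row — the gradient with respect to that input of an attacker
objective ``A``, which is either

* ``"loss"`` — the model's per-sample classification loss at the true
  label, so descending the gradient moves the sample toward correct
  classification, or
* ``"decision_function"`` — the signed margin of the true class against its
  strongest rival, so that for a binary linear model the prescribed descent
  step moves class ``+1`` rows along ``+w`` and class ``-1`` rows along
  ``-w`` (linear models only).

Linear-model gradients are closed form in the fitted coefficients; the
feedforward net computes them by exact backpropagation.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass

import joblib
import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

__all__ = [
    "GradientClassifier",
    "GradientField",
    "LinearSVMClassifier",
    "LogisticRegressionClassifier",
    "FeedforwardNetClassifier",
    "make_model",
    "model_tag",
    "MODEL_REGISTRY",
    "save_model",
    "load_model",
]

OBJECTIVES = ("loss", "decision_function")


@dataclass
class GradientField:
    """Per-sample input gradients for one block of samples."""

    G: np.ndarray
    objective: str
    model_tag: str

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if not np.all(np.isfinite(self.G)):
            raise ValueError("gradient field contains non-finite entries")


class GradientClassifier(abc.ABC):
    """Common contract: fit / predict / per-sample input gradient."""

    tag: str = "base"
    #: whether the decision_function attacker objective is available
    supports_decision_gradient: bool = False
    #: whether nested CV may grid-search an L2 strength C for this model
    supports_C_grid: bool = False

    def __init__(self) -> None:
        self.classes_: np.ndarray | None = None
        self.n_features_: int | None = None

    # -- subclass hooks ----------------------------------------------------
    @abc.abstractmethod
    def _fit(self, X: np.ndarray, y: np.ndarray) -> None: ...

    @abc.abstractmethod
    def _scores(self, X: np.ndarray) -> np.ndarray:
        """Per-class scores, shape (n, K); higher = more likely."""

    @abc.abstractmethod
    def _input_gradient(self, X: np.ndarray, y: np.ndarray | None, objective: str) -> np.ndarray: ...

    @abc.abstractmethod
    def clone(self) -> "GradientClassifier":
        """Fresh unfitted copy with identical hyperparameters."""

    # -- shared surface ----------------------------------------------------
    @property
    def is_fitted(self) -> bool:
        return self.classes_ is not None

    def fit(self, X, y) -> "GradientClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("training set must be a non-empty 2-D matrix")
        if y.shape != (X.shape[0],):
            raise ValueError("label count does not match sample count")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError(f"training fold contains a single class ({classes})")
        self.classes_ = classes
        self.n_features_ = X.shape[1]
        self._fit(X, y.astype(int))
        return self

    def _check_block(self, X) -> np.ndarray:
        if not self.is_fitted:
            raise RuntimeError(f"{self.tag} model is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_:
            raise ValueError(
                f"feature count mismatch: model expects {self.n_features_}, got {X.shape[1]}"
            )
        return X

    def predict(self, X) -> np.ndarray:
        """One label per row; score ties go to the lowest class index."""
        X = self._check_block(X)
        S = self._scores(X)
        return self.classes_[np.argmax(S, axis=1)]

    def input_gradient(self, X, y=None, objective: str = "loss") -> GradientField:
        X = self._check_block(X)
        if objective not in OBJECTIVES:
            raise ValueError(f"unknown objective '{objective}'")
        if objective == "decision_function" and not self.supports_decision_gradient:
            raise ValueError(
                f"model '{self.tag}' supports only the loss objective for input gradients"
            )
        if y is None:
            raise ValueError("true labels are required to compute the attacker gradient")
        y = np.asarray(y).astype(int)
        if y.shape != (X.shape[0],):
            raise ValueError("label count does not match block row count")
        G = self._input_gradient(X, y, objective)
        return GradientField(G=G, objective=objective, model_tag=self.tag)


# ---------------------------------------------------------------------------
# Linear adapters (scikit-learn fits, closed-form input gradients)


class _LinearAdapter(GradientClassifier):
    supports_decision_gradient = True
    supports_C_grid = True

    def __init__(self, C: float = 1.0, seed: int = 0) -> None:
        super().__init__()
        if C <= 0:
            raise ValueError("C must be positive")
        self.C = float(C)
        self.seed = int(seed)
        self._est = None

    def _coef_matrix(self) -> np.ndarray:
        """Coefficients as (K, p); binary models expanded to [-w/?, +w] rows
        are never needed — binary paths are handled explicitly."""
        return np.asarray(self._est.coef_, dtype=float)

    @property
    def _binary(self) -> bool:
        return self.classes_.size == 2

    def _signed(self, y: np.ndarray) -> np.ndarray:
        """Map binary labels onto {-1, +1} by class order."""
        return np.where(y == self.classes_[1], 1.0, -1.0)

    def _margin_pair(self, X: np.ndarray, y: np.ndarray):
        """True-class score, strongest-rival score and rival index, multiclass."""
        S = self._scores(X)
        idx = np.searchsorted(self.classes_, y)
        S_rival = S.copy()
        S_rival[np.arange(len(y)), idx] = -np.inf
        rival = np.argmax(S_rival, axis=1)
        return S[np.arange(len(y)), idx], S_rival[np.arange(len(y)), rival], idx, rival

    def _decision_gradient(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        W = self._coef_matrix()
        if self._binary:
            w = W[0]
            return np.outer(-self._signed(y), w)
        _, _, idx, rival = self._margin_pair(X, y)
        # descending G raises the true-vs-rival margin s_true - s_rival
        return W[rival] - W[idx]

    def per_sample_loss(self, X, y) -> np.ndarray:
        """The scalar per-sample loss whose input gradient loss mode returns."""
        X = self._check_block(X)
        return self._loss_values(X, np.asarray(y).astype(int))


class LinearSVMClassifier(_LinearAdapter):
    """Linear SVM (hinge loss, L2 regularization, one-vs-rest for K > 2).

    The loss-mode attacker objective is the per-sample multiclass hinge
    ``max(0, 1 + s_rival - s_true)`` on the fitted decision scores (binary:
    ``max(0, 1 - y_pm * f(x))``), whose input gradient is closed form in the
    coefficient rows.
    """

    tag = "svm"

    def _fit(self, X, y) -> None:
        self._est = LinearSVC(C=self.C, max_iter=5000, random_state=self.seed)
        self._est.fit(X, y)

    def _scores(self, X) -> np.ndarray:
        f = self._est.decision_function(X)
        if f.ndim == 1:  # binary: score of class order [c0, c1] is [-f, f]
            return np.column_stack([-f, f])
        return f

    def _input_gradient(self, X, y, objective) -> np.ndarray:
        if objective == "decision_function":
            return self._decision_gradient(X, y)
        W = self._coef_matrix()
        if self._binary:
            ypm = self._signed(y)
            f = self._est.decision_function(X)
            active = (1.0 - ypm * f) > 0
            return np.outer(-ypm * active, W[0])
        s_true, s_rival, idx, rival = self._margin_pair(X, y)
        active = (1.0 + s_rival - s_true) > 0
        return (W[rival] - W[idx]) * active[:, None]

    def _loss_values(self, X, y) -> np.ndarray:
        if self._binary:
            f = self._est.decision_function(X)
            return np.maximum(0.0, 1.0 - self._signed(y) * f)
        s_true, s_rival, _, _ = self._margin_pair(X, y)
        return np.maximum(0.0, 1.0 + s_rival - s_true)

    def clone(self) -> "LinearSVMClassifier":
        return LinearSVMClassifier(C=self.C, seed=self.seed)


class LogisticRegressionClassifier(_LinearAdapter):
    """L2-regularized (multinomial) logistic regression.

    Loss mode differentiates the per-sample cross-entropy ``-log p_y(x)``,
    giving ``sum_k (p_k - [k = y]) w_k``.
    """

    tag = "logreg"

    def _fit(self, X, y) -> None:
        self._est = LogisticRegression(C=self.C, max_iter=1000, random_state=self.seed)
        self._est.fit(X, y)

    def _scores(self, X) -> np.ndarray:
        return self._est.predict_proba(X)

    def _input_gradient(self, X, y, objective) -> np.ndarray:
        if objective == "decision_function":
            return self._decision_gradient(X, y)
        P = self._est.predict_proba(X)
        idx = np.searchsorted(self.classes_, y)
        W = self._coef_matrix()
        if self._binary:
            p1 = P[:, 1]
            y1 = (idx == 1).astype(float)
            return (p1 - y1)[:, None] * W[0][None, :]
        Y = np.zeros_like(P)
        Y[np.arange(len(y)), idx] = 1.0
        return (P - Y) @ W

    def _loss_values(self, X, y) -> np.ndarray:
        P = self._est.predict_proba(X)
        idx = np.searchsorted(self.classes_, y)
        return -np.log(np.clip(P[np.arange(len(y)), idx], 1e-300, None))

    def clone(self) -> "LogisticRegressionClassifier":
        return LogisticRegressionClassifier(C=self.C, seed=self.seed)


# ---------------------------------------------------------------------------
# Feedforward net (numpy, exact backprop)


class FeedforwardNetClassifier(GradientClassifier):
    """Three fully connected layers with ReLU activations, trained with
    cross-entropy and Adam (lr 1e-3, batch 10, 10 epochs by default).

    Implemented directly in numpy so the per-sample input gradient of the
    cross-entropy loss is available in closed form via backpropagation.
    All randomness (weight init, batch order) is keyed to ``seed``.
    """

    tag = "fnn"
    supports_decision_gradient = False
    supports_C_grid = False

    def __init__(
        self,
        hidden_sizes: tuple[int, ...] = (64, 32),
        learning_rate: float = 1e-3,
        batch_size: int = 10,
        epochs: int = 10,
        seed: int = 0,
    ) -> None:
        super().__init__()
        if not hidden_sizes:
            raise ValueError("hidden_sizes must be non-empty")
        if learning_rate <= 0 or batch_size < 1 or epochs < 1:
            raise ValueError("invalid training hyperparameters")
        self.hidden_sizes = tuple(int(h) for h in hidden_sizes)
        self.learning_rate = float(learning_rate)
        self.batch_size = int(batch_size)
        self.epochs = int(epochs)
        self.seed = int(seed)
        self._params: list[tuple[np.ndarray, np.ndarray]] | None = None

    # -- forward / backward -------------------------------------------------
    def _forward(self, X: np.ndarray):
        """Return (activations, pre-activations); ``As[li]`` is the input of
        layer ``li`` and ``Zs[li]`` its pre-activation output."""
        A, Zs, As = X, [], [X]
        n_layers = len(self._params)
        for li, (W, b) in enumerate(self._params):
            Z = A @ W + b
            Zs.append(Z)
            A = np.maximum(Z, 0.0) if li < n_layers - 1 else Z
            As.append(A)
        return As, Zs

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def _fit(self, X, y) -> None:
        rng = np.random.default_rng(self.seed)
        idx = np.searchsorted(self.classes_, y)
        K = self.classes_.size
        sizes = [X.shape[1], *self.hidden_sizes, K]
        self._params = []
        for d_in, d_out in zip(sizes[:-1], sizes[1:]):
            W = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
            self._params.append((W, np.zeros(d_out)))
        # Adam state
        m = [(np.zeros_like(W), np.zeros_like(b)) for W, b in self._params]
        v = [(np.zeros_like(W), np.zeros_like(b)) for W, b in self._params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0
        n = X.shape[0]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                batch = order[start : start + self.batch_size]
                Xb, yb = X[batch], idx[batch]
                As, Zs = self._forward(Xb)
                P = self._softmax(As[-1])
                delta = P.copy()
                delta[np.arange(len(yb)), yb] -= 1.0
                delta /= len(yb)
                grads = []
                for li in range(len(self._params) - 1, -1, -1):
                    W, _ = self._params[li]
                    gW = As[li].T @ delta
                    gb = delta.sum(axis=0)
                    grads.append((gW, gb))
                    if li > 0:
                        delta = (delta @ W.T) * (Zs[li - 1] > 0)
                grads.reverse()
                t += 1
                new_params = []
                for li, ((W, b), (gW, gb)) in enumerate(zip(self._params, grads)):
                    mW, mb = m[li]
                    vW, vb = v[li]
                    mW = b1 * mW + (1 - b1) * gW
                    mb = b1 * mb + (1 - b1) * gb
                    vW = b2 * vW + (1 - b2) * gW**2
                    vb = b2 * vb + (1 - b2) * gb**2
                    m[li], v[li] = (mW, mb), (vW, vb)
                    mW_h, mb_h = mW / (1 - b1**t), mb / (1 - b1**t)
                    vW_h, vb_h = vW / (1 - b2**t), vb / (1 - b2**t)
                    W = W - self.learning_rate * mW_h / (np.sqrt(vW_h) + eps)
                    b = b - self.learning_rate * mb_h / (np.sqrt(vb_h) + eps)
                    new_params.append((W, b))
                self._params = new_params

    def _scores(self, X) -> np.ndarray:
        As, _ = self._forward(X)
        return As[-1]

    def predict_proba(self, X) -> np.ndarray:
        X = self._check_block(X)
        return self._softmax(self._scores(X))

    def per_sample_loss(self, X, y) -> np.ndarray:
        """Cross-entropy -log p_y per row (the loss the gradient descends)."""
        X = self._check_block(X)
        idx = np.searchsorted(self.classes_, np.asarray(y).astype(int))
        P = self._softmax(self._scores(X))
        return -np.log(np.clip(P[np.arange(len(idx)), idx], 1e-300, None))

    def _input_gradient(self, X, y, objective) -> np.ndarray:
        # objective validation upstream guarantees loss mode here
        idx = np.searchsorted(self.classes_, y)
        As, Zs = self._forward(X)
        P = self._softmax(As[-1])
        delta = P.copy()
        delta[np.arange(len(idx)), idx] -= 1.0
        for li in range(len(self._params) - 1, -1, -1):
            W, _ = self._params[li]
            delta = delta @ W.T
            if li > 0:
                delta = delta * (Zs[li - 1] > 0)
        return delta

    def clone(self) -> "FeedforwardNetClassifier":
        return FeedforwardNetClassifier(
            hidden_sizes=self.hidden_sizes,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            seed=self.seed,
        )


# ---------------------------------------------------------------------------
# Registry

MODEL_REGISTRY = {
    "svm": LinearSVMClassifier,
    "logreg": LogisticRegressionClassifier,
    "fnn": FeedforwardNetClassifier,
}


def model_tag(spec) -> str:
    """Canonical tag of a model spec (string name or dict with 'name')."""
    if isinstance(spec, str):
        name = spec
    elif isinstance(spec, dict):
        name = spec.get("name", "")
    elif isinstance(spec, GradientClassifier):
        return spec.tag
    else:
        raise ValueError(f"cannot interpret model spec {spec!r}")
    if name not in MODEL_REGISTRY:
        raise ValueError(f"unknown model '{name}'; registered: {sorted(MODEL_REGISTRY)}")
    return name


def make_model(spec, seed: int | None = None, **overrides) -> GradientClassifier:
    """Instantiate a fresh classifier from a spec.

    ``spec`` is a registry name (``"svm"``, ``"logreg"``, ``"fnn"``), a dict
    ``{"name": ..., <hyperparameters>}``, or an existing instance (cloned).
    ``seed`` and keyword overrides take precedence over spec entries.
    """
    if isinstance(spec, GradientClassifier):
        model = spec.clone()
        if seed is not None:
            model.seed = int(seed)
        return model
    params = dict(spec) if isinstance(spec, dict) else {}
    params.pop("name", None)
    params.update(overrides)
    if seed is not None:
        params["seed"] = int(seed)
    cls = MODEL_REGISTRY[model_tag(spec)]
    return cls(**params)


def save_model(model: GradientClassifier, path) -> None:
    """Persist a (possibly fitted) adapter for reuse, e.g. transfer studies."""
    joblib.dump(model, path)


def load_model(path) -> GradientClassifier:
    model = joblib.load(path)
    if not isinstance(model, GradientClassifier):
        raise ValueError(f"{path} does not contain a GradientClassifier")
    return model
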