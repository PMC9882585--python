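"""Dataset container, connectome feature construction, fold planning and similarity auditing.

The central object is :class:`Dataset` — a samples x features matrix ``X``
with integer class labels ``y`` (contiguous ``0..K-1``).  Both attack
algorithms rewrite ``X`` fold by fold and never touch ``y``.

Connectome features follow standard functional-connectivity practice: node
time series are correlated pairwise (Pearson), Fisher z-transformed, and the
strict upper triangle of the resulting symmetric matrix is vectorized
row-major into one feature vector per subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "Dataset",
    "FoldPlan",
    "SimilarityReport",
    "build_connectome",
    "vectorize_upper",
    "devectorize_upper",
    "chance_level",
    "feature_similarity",
    "make_fold_plan",
    "read_dataset",
    "write_dataset",
    "derive_seed",
]

#: default clip applied to correlations before atanh so Fisher z stays finite
DEFAULT_CORR_CLIP = 0.999999


def derive_seed(seed: int, *keys: int) -> int:
    """Derive a stable sub-seed (< 2**31) from a base seed and integer keys."""
    ss = np.random.SeedSequence([int(seed)] + [int(k) for k in keys])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class Dataset:
    """A labeled feature matrix.

    Parameters
    ----------
    X : ndarray of shape (n_samples, n_features)
        Feature values; must be finite.
    y : ndarray of shape (n_samples,)
        Integer class labels ``0..K-1``; every class present at least once.
    feature_names, sample_ids : optional sequences of str
    label_names : optional sequence
        Original label of class ``k`` at position ``k`` (kept so reports can
        use the names the labels file carried before integer mapping).
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] | None = None
    sample_ids: list[str] | None = None
    label_names: list | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError(f"X must be 2-D, got ndim={self.X.ndim}")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        n, p = self.X.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if p < 1:
            raise ValueError("need at least 1 feature")
        if self.y.shape != (n,):
            raise ValueError(
                f"label count {self.y.shape[0] if self.y.ndim == 1 else self.y.shape} "
                f"does not match {n} samples"
            )
        if not np.issubdtype(self.y.dtype, np.integer):
            if np.any(self.y != np.floor(self.y)):
                raise ValueError("labels must be integers; use Dataset.from_arrays to map them")
            self.y = self.y.astype(int)
        classes = np.unique(self.y)
        if classes.size < 2:
            raise ValueError("need at least 2 classes")
        if not np.array_equal(classes, np.arange(classes.size)):
            raise ValueError(
                f"labels must be contiguous 0..K-1 with every class present; got {classes}. "
                "Use Dataset.from_arrays to map arbitrary labels."
            )
        if self.feature_names is not None and len(self.feature_names) != p:
            raise ValueError("feature_names length does not match n_features")
        if self.sample_ids is not None and len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match n_samples")

    @classmethod
    def from_arrays(cls, X, y_raw, feature_names=None, sample_ids=None) -> "Dataset":
        """Build a Dataset, mapping arbitrary labels to contiguous ``0..K-1``.

        The sorted unique raw labels define the mapping and are stored as
        ``label_names``.
        """
        y_raw = np.asarray(y_raw)
        classes, y = np.unique(y_raw, return_inverse=True)
        return cls(
            X=np.asarray(X, dtype=float),
            y=y.astype(int),
            feature_names=feature_names,
            sample_ids=sample_ids,
            label_names=list(classes),
        )

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.y.max()) + 1

    def copy(self) -> "Dataset":
        return Dataset(
            X=self.X.copy(),
            y=self.y.copy(),
            feature_names=None if self.feature_names is None else list(self.feature_names),
            sample_ids=None if self.sample_ids is None else list(self.sample_ids),
            label_names=None if self.label_names is None else list(self.label_names),
        )

    def with_X(self, X_new: np.ndarray) -> "Dataset":
        """A new Dataset sharing labels/metadata but with replaced features."""
        out = self.copy()
        out.X = np.asarray(X_new, dtype=float)
        if out.X.shape != self.X.shape:
            raise ValueError("replacement X must keep the original shape")
        return out


@dataclass
class FoldPlan:
    """A K-fold partition of ``n`` samples: ``assignments[i]`` is the fold
    holding sample ``i`` out."""

    n_folds: int
    assignments: np.ndarray
    stratified: bool
    seed: int

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)
        folds = np.unique(self.assignments)
        if not np.array_equal(folds, np.arange(self.n_folds)):
            raise ValueError("every fold must be non-empty and indexed 0..n_folds-1")

    @property
    def n_samples(self) -> int:
        return self.assignments.size

    def held_out(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == k)

    def training(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != k)

    def __iter__(self):
        for k in range(self.n_folds):
            yield self.training(k), self.held_out(k)


@dataclass
class SimilarityReport:
    """Pearson audit of an enhanced matrix against the original."""

    r: float
    max_abs_change: float
    per_sample_r: np.ndarray | None = None


def build_connectome(node_timeseries: np.ndarray, clip: float = DEFAULT_CORR_CLIP) -> np.ndarray:
    """Pearson-correlate node time series and Fisher-z transform.

    Parameters
    ----------
    node_timeseries : ndarray of shape (T, N)
        T time points for N nodes.
    clip : float
        Correlations are clipped to ``[-clip, clip]`` before ``atanh`` so
        perfectly (anti-)correlated pairs stay finite.

    Returns
    -------
    ndarray of shape (N, N)
        Symmetric Fisher-z connectivity matrix with zero diagonal.
    """
    ts = np.asarray(node_timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("node_timeseries must be a T x N matrix")
    T, N = ts.shape
    if T < 3:
        raise ValueError(f"need at least 3 time points, got {T}")
    if N < 2:
        raise ValueError(f"need at least 2 nodes, got {N}")
    if not np.all(np.isfinite(ts)):
        raise ValueError("node_timeseries contains non-finite values")
    sd = ts.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance node series at node index {dead[0]}")
    if not 0 < clip < 1:
        raise ValueError("clip must lie in (0, 1)")
    R = np.corrcoef(ts, rowvar=False)
    R = np.clip(R, -clip, clip)
    Z = np.arctanh(R)
    Z = (Z + Z.T) / 2.0  # enforce exact symmetry against rounding
    np.fill_diagonal(Z, 0.0)
    return Z


def vectorize_upper(matrix: np.ndarray) -> np.ndarray:
    """Strict upper triangle of a square matrix, row-major, length N(N-1)/2."""
    M = np.asarray(matrix)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"matrix must be square, got shape {M.shape}")
    N = M.shape[0]
    if N < 2:
        raise ValueError("matrix must be at least 2 x 2")
    iu = np.triu_indices(N, k=1)
    return M[iu].copy()


def devectorize_upper(vector: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize_upper` for symmetric zero-diagonal matrices."""
    v = np.asarray(vector, dtype=float).ravel()
    L = v.size
    N = int(round((1 + np.sqrt(1 + 8 * L)) / 2))
    if N * (N - 1) // 2 != L:
        raise ValueError(f"length {L} is not a triangular number N(N-1)/2")
    M = np.zeros((N, N), dtype=float)
    iu = np.triu_indices(N, k=1)
    M[iu] = v
    M += M.T
    return M


def chance_level(y) -> float:
    """Proportion of the most frequent class — the majority-vote baseline."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("y is empty")
    _, counts = np.unique(y, return_counts=True)
    return float(counts.max() / y.size)


def feature_similarity(X_orig, X_enh, per_sample: bool = False) -> SimilarityReport:
    """Pearson correlation between two feature matrices, flattened entry-wise.

    The headline ``r`` treats the full samples x features matrix as one long
    vector; ``per_sample=True`` additionally reports per-row correlations.
    """
    A = np.asarray(X_orig, dtype=float)
    B = np.asarray(X_enh, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    a, b = A.ravel(), B.ravel()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance matrix; Pearson correlation undefined")
    if np.array_equal(a, b):
        r = 1.0
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    per_row = None
    if per_sample:
        if A.ndim != 2:
            raise ValueError("per-sample correlations need 2-D input")
        per_row = np.empty(A.shape[0])
        for i in range(A.shape[0]):
            ra, rb = A[i], B[i]
            if ra.std() == 0 or rb.std() == 0:
                per_row[i] = np.nan
            elif np.array_equal(ra, rb):
                per_row[i] = 1.0
            else:
                per_row[i] = np.corrcoef(ra, rb)[0, 1]
    return SimilarityReport(
        r=r,
        max_abs_change=float(np.max(np.abs(A - B))),
        per_sample_r=per_row,
    )


def make_fold_plan(y, n_folds: int, stratified: bool = True, seed: int = 0) -> FoldPlan:
    """Partition samples into K folds, stratified by class when feasible.

    If ``stratified`` is requested but the smallest class has fewer than
    ``n_folds`` members, the plan degrades to an unstratified shuffled
    K-fold split (with a warning) rather than failing.
    """
    y = np.asarray(y)
    n = y.size
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds n_samples={n}")
    use_strat = stratified
    if stratified:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < n_folds:
            warnings.warn(
                f"smallest class has {counts.min()} members < n_folds={n_folds}; "
                "falling back to unstratified folds",
                stacklevel=2,
            )
            use_strat = False
    if use_strat:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignments = np.empty(n, dtype=int)
    for k, (_, held) in enumerate(splitter.split(np.zeros((n, 1)), y)):
        assignments[held] = k
    return FoldPlan(n_folds=n_folds, assignments=assignments, stratified=use_strat, seed=seed)


# ---------------------------------------------------------------------------
# File I/O: delimited text (CSV/TSV) and .npy array containers.

_TEXT_EXT = {".csv", ".tsv", ".txt"}


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() == ".tsv" else ","


def _read_matrix(path: Path) -> tuple[np.ndarray, list[str] | None]:
    if path.suffix.lower() == ".npy":
        return np.load(path), None
    if path.suffix.lower() not in _TEXT_EXT:
        raise ValueError(f"unknown feature-file extension '{path.suffix}' for {path}")
    sep = _delimiter_for(path)
    with open(path) as fh:
        first = fh.readline()
    has_header = False
    for tok in first.strip().split(sep):
        try:
            float(tok)
        except ValueError:
            has_header = True
            break
    try:
        df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
    except ValueError as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        raise ValueError(f"non-numeric values in feature file {path}")
    names = [str(c) for c in df.columns] if has_header else None
    return df.to_numpy(dtype=float), names


def _read_labels(path: Path) -> np.ndarray:
    if path.suffix.lower() == ".npy":
        return np.load(path)
    if path.suffix.lower() not in _TEXT_EXT:
        raise ValueError(f"unknown label-file extension '{path.suffix}' for {path}")
    raw = []
    with open(path) as fh:
        for line in fh:
            tok = line.strip()
            if tok:
                raw.append(tok)
    if raw and not raw[0].lstrip("-").isdigit():
        # allow a single header line such as "label"
        try:
            int(raw[0])
        except ValueError:
            raw = raw[1:]
    try:
        return np.array([int(t) for t in raw])
    except ValueError:
        return np.array(raw)


def read_dataset(path_features, path_labels) -> Dataset:
    """Load features + labels from disk into a :class:`Dataset`.

    Features: CSV/TSV (header optional) or ``.npy``. Labels: single-column
    text or ``.npy``. Arbitrary labels are mapped to ``0..K-1`` with the
    original names retained.
    """
    pf, pl = Path(path_features), Path(path_labels)
    X, names = _read_matrix(pf)
    y_raw = _read_labels(pl)
    if X.shape[0] != y_raw.shape[0]:
        raise ValueError(
            f"feature rows ({X.shape[0]}) and label rows ({y_raw.shape[0]}) disagree"
        )
    return Dataset.from_arrays(X, y_raw, feature_names=names)


def write_dataset(dataset: Dataset, path_features, path_labels=None) -> None:
    """Write a dataset to disk; CSV round-trips at full double precision,
    ``.npy`` bit-exactly."""
    pf = Path(path_features)
    pl = Path(path_labels) if path_labels is not None else pf.with_suffix(".labels.csv")
    if pf.suffix.lower() == ".npy":
        np.save(pf, dataset.X)
    elif pf.suffix.lower() in _TEXT_EXT:
        sep = _delimiter_for(pf)
        header = dataset.feature_names or [f"f{j}" for j in range(dataset.n_features)]
        df = pd.DataFrame(dataset.X, columns=header)
        df.to_csv(pf, sep=sep, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown feature-file extension '{pf.suffix}'")
    labels = dataset.y
    if dataset.label_names is not None:
        labels = np.asarray([dataset.label_names[k] for k in dataset.y])
    if pl.suffix.lower() == ".npy":
        np.save(pl, labels)
    else:
        pd.Series(labels, name="label").to_csv(pl, index=False)
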