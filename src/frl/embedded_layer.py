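"""Embedded layer: recursive feature elimination wrapped around a
from-scratch logistic regression, with stratified K-fold cross-validation.

The classifier is plain binary logistic regression trained by full-batch
gradient descent on the mean cross-entropy cost

    J(w, b) = (1/m) sum_i -[ y_i ln a_i + (1 - y_i) ln(1 - a_i) ],

with ``a = sigmoid(Xw + b)`` and an optional L2 penalty.  RFE repeatedly
fits the model on each training fold, ranks features by the mean absolute
(standardized) weight across folds, and drops the ``pace`` weakest
features until a floor is reached.  The elimination pace is keyed to the
post-filter dimensionality ``d1``: 5 above 2000 features, 3 between 1000
and 2000, 2 at or below 1000.

``run_frl`` chains the Fisher filter layer and this embedded layer into
the full pipeline and evaluates the selected subset on held-out folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .expression_io import ExpressionMatrix
from .filter_layer import FisherRanking, apply_filter, rank_genes


def sigmoid(j):
    """Numerically stable logistic function 1 / (1 + e^-j).

    Inputs are clipped to +-700 before exponentiation and the output is
    kept strictly inside (0, 1) so downstream logs never see 0 or 1.
    """
    j = np.clip(np.asarray(j, dtype=float), -700.0, 700.0)
    out = 1.0 / (1.0 + np.exp(-j))
    return np.minimum(out, np.nextafter(1.0, 0.0))


def logistic_cost(a, y, clip: float = 1e-12) -> float:
    """Mean binary cross-entropy of predicted probabilities ``a``."""
    a = np.asarray(a, dtype=float)
    y = np.asarray(y, dtype=float)
    if a.shape != y.shape:
        raise ValueError("predictions and labels must have the same length")
    a = np.clip(a, clip, 1.0 - clip)
    return float(np.mean(-(y * np.log(a) + (1.0 - y) * np.log(1.0 - a))))


def logistic_gradient(X, y, w, b, l2: float = 0.0):
    """Analytic gradient of the (optionally L2-penalized) cost.

    The penalty is ``l2 * ||w||^2 / 2`` added to the mean cross-entropy,
    so duplicating every sample leaves the optimum unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    m = X.shape[0]
    resid = sigmoid(X @ w + b) - y
    gw = X.T @ resid / m + l2 * np.asarray(w)
    gb = float(resid.mean())
    return gw, gb


@dataclass
class TrainConfig:
    """Hyperparameters for gradient-descent logistic training."""

    learning_rate: float = 0.1
    max_iter: int = 2000
    tol: float = 1e-7
    clip: float = 1e-12
    l2: float = 0.0


@dataclass
class LogisticModel:
    """Fitted weights/bias plus the per-iteration cost trace."""

    weights: np.ndarray
    bias: float
    training_trace: list[float]
    feature_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.feature_ids is not None and len(self.feature_ids) != self.weights.size:
            raise ValueError("feature_ids must align with weights")
        trace = np.asarray(self.training_trace, dtype=float)
        if trace.size > 1 and np.any(np.diff(trace) > 1e-9):
            raise ValueError("training cost trace is not non-increasing")

    def decision_function(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.bias

    def predict_proba(self, X) -> np.ndarray:
        return sigmoid(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


def _penalized_cost(X, y, w, b, hp: TrainConfig) -> float:
    a = sigmoid(X @ w + b)
    cost = logistic_cost(a, y, hp.clip)
    if hp.l2:
        cost += hp.l2 * float(w @ w) / 2.0
    return cost


def fit_logistic(X, y, hp: TrainConfig | None = None,
                 feature_ids: list[str] | None = None) -> LogisticModel:
    """Train logistic regression by full-batch gradient descent.

    Starts from zero weights and takes steps of size ``hp.learning_rate``;
    whenever a step would increase the cost the step size is halved
    (deterministic backtracking), which keeps the cost trace monotone even
    on wide matrices.  Stops when the cost improvement drops below
    ``hp.tol`` or after ``hp.max_iter`` iterations.
    """
    hp = hp or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be samples x features aligned with y")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit the classifier")

    w = np.zeros(X.shape[1])
    b = 0.0
    lr = hp.learning_rate
    cost = _penalized_cost(X, y, w, b, hp)
    trace = [cost]
    for _ in range(hp.max_iter):
        gw, gb = logistic_gradient(X, y, w, b, hp.l2)
        if not (np.all(np.isfinite(gw)) and np.isfinite(gb)):
            raise FloatingPointError(
                "non-finite gradient; reduce the learning rate"
            )
        for _halving in range(64):
            w_new = w - lr * gw
            b_new = b - lr * gb
            new_cost = _penalized_cost(X, y, w_new, b_new, hp)
            if new_cost <= cost + 1e-12:
                break
            lr *= 0.5
        else:
            break  # step underflow: already at (numerical) optimum
        w, b = w_new, b_new
        improvement = cost - new_cost
        cost = new_cost
        trace.append(cost)
        if improvement < hp.tol:
            break
    return LogisticModel(w, b, trace, feature_ids)


def choose_pace(d1: int) -> int:
    """Elimination pace keyed to the post-filter dimensionality.

    5 above 2000 features, 3 for 1000 < d1 <= 2000, 2 for d1 <= 1000
    (boundaries resolve to the finer pace).
    """
    if d1 < 1:
        raise ValueError("d1 must be positive")
    if d1 > 2000:
        return 5
    if d1 > 1000:
        return 3
    return 2


def kfold_split(n_samples: int, labels, K: int, seed: int) -> list[np.ndarray]:
    """Stratified K folds: disjoint, covering, class-balanced, seeded.

    Each class is shuffled and dealt round-robin across folds, so fold
    sizes differ by at most one both overall and within each class.
    """
    labels = np.asarray(labels)
    if K < 2:
        raise ValueError("K must be at least 2")
    if labels.size != n_samples:
        raise ValueError("labels must have length n_samples")
    for k in np.unique(labels):
        n_k = int(np.sum(labels == k))
        if n_k < K:
            raise ValueError(f"class {k} has only {n_k} samples, fewer than K={K}")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(K)]
    ptr = 0
    for k in np.unique(labels):
        idx = np.flatnonzero(labels == k)
        rng.shuffle(idx)
        for i in idx:
            folds[ptr % K].append(int(i))
            ptr += 1
    return [np.array(sorted(f), dtype=int) for f in folds]


def _standardize(train: np.ndarray, other: np.ndarray):
    """Z-score both blocks with training statistics only (no leakage)."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (train - mu) / sd, (other - mu) / sd


@dataclass
class RfeStep:
    """One RFE iteration: the surviving set and its cross-validated metrics."""

    feature_ids: list[str]
    cv_accuracy: float
    cv_f1: float
    oof_scores: np.ndarray = field(repr=False, default=None)


@dataclass
class RfePath:
    """The full elimination trajectory and the chosen subset (``A_2``)."""

    steps: list[RfeStep]
    pace: int
    folds: int
    best_step: int
    selected_features: list[str]


def _cv_fit(X: np.ndarray, y: np.ndarray, folds: list[np.ndarray],
            hp: TrainConfig):
    """Per-fold logistic fits; returns pooled out-of-fold scores,
    accuracy, F1, and the mean |weight| importance across folds."""
    n, p = X.shape
    oof = np.empty(n)
    importance = np.zeros(p)
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        X_tr, X_va = _standardize(X[mask], X[fold])
        model = fit_logistic(X_tr, y[mask], hp)
        oof[fold] = model.predict_proba(X_va)
        importance += np.abs(model.weights)
    importance /= len(folds)
    pred = (oof >= 0.5).astype(int)
    acc = float(np.mean(pred == y))
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return oof, acc, f1, importance


def rfe(mat: ExpressionMatrix, pace: int, K: int, floor: int,
        hp: TrainConfig | None = None, seed: int = 0,
        force_floor: bool = False) -> RfePath:
    """Recursive feature elimination over the genes of ``mat``.

    Each step fits the classifier on every training fold, records the
    pooled out-of-fold accuracy/F1 of the surviving set, then eliminates
    the ``pace`` features with the smallest mean absolute standardized
    weight (the last step may drop fewer to land exactly on ``floor``).
    Ties in importance keep the lexicographically smaller gene id.

    The chosen subset maximizes CV accuracy, preferring the smaller set on
    ties; with ``force_floor`` the floor-sized final set is chosen
    regardless (used when an exact target dimensionality is requested).
    """
    if floor < 1:
        raise ValueError("floor must be at least 1")
    if pace < 1:
        raise ValueError("pace must be at least 1")
    hp = hp or TrainConfig()
    y = mat.require_labels().astype(float)
    folds = kfold_split(mat.n_samples, y, K, seed)
    X_full = mat.values.T  # samples x genes
    current = list(mat.gene_ids)
    col = {g: i for i, g in enumerate(mat.gene_ids)}

    steps: list[RfeStep] = []
    while True:
        X = X_full[:, [col[g] for g in current]]
        oof, acc, f1, importance = _cv_fit(X, y, folds, hp)
        steps.append(RfeStep(list(current), acc, f1, oof))
        if len(current) <= floor:
            break
        n_drop = min(pace, len(current) - floor)
        # ascending importance; on ties the larger gene id is dropped first
        order = sorted(range(len(current)),
                       key=lambda i: (importance[i],
                                      _reverse_lex(current[i])))
        drop = {current[i] for i in order[:n_drop]}
        current = [g for g in current if g not in drop]

    if force_floor:
        best = len(steps) - 1
    else:
        best = 0
        for i, step in enumerate(steps):
            # strictly decreasing sizes: a later step with equal accuracy
            # is the smaller subset
            if step.cv_accuracy >= steps[best].cv_accuracy:
                best = i
    return RfePath(steps, pace, K, best, list(steps[best].feature_ids))


def _reverse_lex(s: str) -> tuple:
    # sort key that orders strings in reverse lexicographic order
    return tuple(-ord(c) for c in s)


@dataclass
class FRLConfig:
    """Configuration for the full filter + embedded pipeline.

    ``target_dim`` pins the size of the selected subset exactly (78 is the
    conventional standard dimensionality for cross-method comparisons);
    set it to ``None`` to let CV accuracy choose the subset size down to
    ``floor``.
    """

    min_keep: int = 50
    max_keep: int = 4000
    fisher_denominator: str = "within_class"
    keep: int | None = None            # manual filter cut, overrides the elbow
    target_dim: int | None = 78
    floor: int = 2
    k_folds: int = 4
    pace: int | None = None            # None -> choose_pace(d1)
    seed: int = 0
    train: TrainConfig = field(default_factory=TrainConfig)

    @classmethod
    def from_yaml(cls, path) -> "FRLConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        train = TrainConfig(**raw.pop("train", {}))
        return cls(train=train, **raw)


def run_frl(mat: ExpressionMatrix, cfg: FRLConfig | None = None):
    """Run the full pipeline on a labelled matrix.

    Returns ``(FisherRanking, RfePath, EvaluationReport)``: the filter
    ranking with its elbow cut, the elimination path with the selected
    subset, and held-out-fold metrics (confusion counts, ROC/PR, sample
    distance matrix) of the selected subset.
    """
    from .evaluation import evaluate_selection

    cfg = cfg or FRLConfig()
    ranking = rank_genes(mat, cfg.min_keep, cfg.max_keep,
                         cfg.fisher_denominator, keep=cfg.keep)
    a1 = apply_filter(mat, ranking)
    pace = cfg.pace if cfg.pace is not None else choose_pace(ranking.d1)
    if cfg.target_dim is not None:
        floor = min(cfg.target_dim, ranking.d1)
        force = True
    else:
        floor = cfg.floor
        force = False
    path = rfe(a1, pace, cfg.k_folds, floor, cfg.train, cfg.seed,
               force_floor=force)
    best = path.steps[path.best_step]
    selected = mat.subset_genes(path.selected_features)
    y = mat.require_labels()
    report = evaluate_selection(y, best.oof_scores, selected.values)
    return ranking, path, report
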