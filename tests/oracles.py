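"""Independent brute-force oracles used only by the tests.

Each oracle evaluates the relevant formula literally, term by term, with
plain Python loops or an optimizer unrelated to the package's own code
paths, so agreement is a genuine two-route check.
"""

import numpy as np
from scipy.optimize import minimize


def fisher_oracle(values, labels, denominator="within_class"):
    """Literal evaluation of the Fisher score for one feature."""
    values = [float(v) for v in values]
    labels = list(labels)
    n = len(values)
    mu = sum(values) / n
    num = 0.0
    within = 0.0
    for k in sorted(set(labels)):
        vk = [v for v, lab in zip(values, labels) if lab == k]
        nk = len(vk)
        muk = sum(vk) / nk
        vark = sum((v - muk) ** 2 for v in vk) / nk
        num += nk * (muk - mu) ** 2
        within += nk * vark
    if denominator == "within_class":
        denom = within
    else:
        denom = sum((v - mu) ** 2 for v in values) / n
    if denom < 1e-12:
        return 0.0 if num < 1e-12 else min(num / 1e-12, 1e15)
    return num / denom


def cross_entropy_oracle(a, y):
    """Term-by-term mean cross-entropy."""
    total = 0.0
    for ai, yi in zip(a, y):
        total += -(yi * np.log(ai) + (1 - yi) * np.log(1 - ai))
    return total / len(a)


def auc_pair_oracle(y_true, scores):
    """AUC as the concordant-pair fraction (ties count one half)."""
    pos = [s for s, y in zip(scores, y_true) if y == 1]
    neg = [s for s, y in zip(scores, y_true) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def pr_area_oracle(y_true, scores):
    """Average precision by literal threshold enumeration."""
    thresholds = sorted(set(scores), reverse=True)
    P = sum(y_true)
    area = 0.0
    prev_recall = 0.0
    for t in thresholds:
        pred = [1 if s >= t else 0 for s in scores]
        tp = sum(1 for p, y in zip(pred, y_true) if p == 1 and y == 1)
        fp = sum(1 for p, y in zip(pred, y_true) if p == 1 and y == 0)
        recall = tp / P
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def chord_distance_oracle(scores, min_keep, max_keep):
    """Exhaustive max-chord-distance elbow over all indices."""
    scores = [float(s) for s in scores]
    n = len(scores)
    if n == 1:
        best = 0
    else:
        lo, hi = scores[-1], scores[0]
        span = hi - lo
        best, best_d = 0, 0.0
        for i, s in enumerate(scores):
            x = i / (n - 1)
            y = (s - lo) / span if span > 0 else 0.0
            # perpendicular distance to the chord (0,y0)-(1,y_last), which is
            # the anti-diagonal after min-max normalization
            d = abs(x + y - 1.0) / np.sqrt(2.0)
            if d > best_d + 1e-12:
                best, best_d = i, d
        if best_d <= 1e-12:
            best = 0
    return min(max(best, min_keep), max_keep, n)


def _bfgs_logistic_weights(X, y, l2):
    """Unrelated-optimizer logistic fit on standardized features."""
    n, p = X.shape
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    Xs = (X - mu) / sd

    def objective(theta):
        w, b = theta[:p], theta[p]
        z = Xs @ w + b
        return float(np.mean(np.logaddexp(0.0, z) - y * z)
                     + l2 * (w @ w) / 2.0)

    res = minimize(objective, np.zeros(p + 1), method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 5000})
    return res.x[:p]


def greedy_backward_elimination(X, y, gene_ids, folds, l2=1.0):
    """Exhaustive greedy backward elimination (pace 1) with the mean-|w|
    importance rule; returns the order in which features are eliminated."""
    current = list(gene_ids)
    col = {g: i for i, g in enumerate(gene_ids)}
    n = X.shape[0]
    eliminated = []
    while len(current) > 1:
        imp = np.zeros(len(current))
        cols = [col[g] for g in current]
        for fold in folds:
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            w = _bfgs_logistic_weights(X[mask][:, cols], y[mask], l2)
            imp += np.abs(w)
        imp /= len(folds)
        # lowest importance first; ties drop the lexicographically larger id
        victim = min(range(len(current)),
                     key=lambda i: (imp[i], tuple(-ord(c) for c in current[i])))
        eliminated.append(current[victim])
        current.pop(victim)
    return eliminated, current
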