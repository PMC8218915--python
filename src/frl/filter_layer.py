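"""Fisher-score filter layer.

Every gene is scored by the Fisher score — the ratio of between-class mean
spread to within-class variance — genes are ranked in descending score
order, and the ranking is cut at the elbow ("inflection point") of the
score curve.  The retained sub-matrix (``A_1`` of dimension ``d1``) feeds
the embedded RFE layer.

The Fisher score for one gene with classes ``k = 1..c`` is

    F = sum_k n_k (mu_k - mu)^2 / denominator

where ``n_k`` and ``mu_k`` are the class sample count and class mean,
``mu`` the overall mean.  Two denominator conventions are supported:

* ``"within_class"`` (default): ``sum_k n_k sigma_k^2``, the class-weighted
  within-class variances — the standard Fisher-score form, well defined for
  any number of classes;
* ``"pooled"``: the variance of the gene across the whole dataset,
  a literal reading sometimes seen in applied work.

Variances are population variances (divide by ``n_k``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expression_io import ExpressionMatrix

#: scores with a vanishing denominator but nonzero numerator are capped here
SCORE_CEILING = 1e15
_DENOM_FLOOR = 1e-12


@dataclass
class FisherRanking:
    """Genes in descending Fisher-score order with the elbow cut position.

    ``d1`` (== ``inflection_index``) is the number of genes retained by the
    filter layer.
    """

    gene_ids: list[str]
    scores: np.ndarray
    inflection_index: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.gene_ids) != len(self.scores):
            raise ValueError("gene_ids and scores must align")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be non-increasing")
        if not np.all(np.isfinite(self.scores)) or np.any(self.scores < 0):
            raise ValueError("scores must be finite and non-negative")
        if not 1 <= self.inflection_index <= len(self.scores):
            raise ValueError("inflection_index out of range")

    @property
    def d1(self) -> int:
        return self.inflection_index

    @property
    def kept_gene_ids(self) -> list[str]:
        return self.gene_ids[: self.d1]


def _class_stats(values: np.ndarray, labels: np.ndarray):
    """Per-class (n_k, mean, population variance) along the sample axis."""
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("both classes must be present to compute a Fisher score")
    stats = []
    for k in classes:
        sel = values[..., labels == k]
        stats.append((sel.shape[-1], sel.mean(axis=-1), sel.var(axis=-1)))
    return stats


def _fisher_from_stats(stats, overall_mean):
    num = sum(n_k * (mu_k - overall_mean) ** 2 for n_k, mu_k, _ in stats)
    within = sum(n_k * var_k for n_k, _, var_k in stats)
    return num, within


def fisher_scores(values: np.ndarray, labels: np.ndarray,
                  denominator: str = "within_class") -> np.ndarray:
    """Vectorized Fisher scores for a genes x samples value block."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    labels = np.asarray(labels)
    if values.shape[-1] != len(labels):
        raise ValueError("values and labels must align on samples")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    stats = _class_stats(values, labels)
    mu = values.mean(axis=-1)
    num, within = _fisher_from_stats(stats, mu)
    if denominator == "within_class":
        denom = within
    elif denominator == "pooled":
        denom = values.var(axis=-1)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    num = np.asarray(num, dtype=float)
    denom = np.asarray(denom, dtype=float)
    score = np.zeros_like(num)
    ok = denom >= _DENOM_FLOOR
    score[ok] = num[ok] / denom[ok]
    # degenerate denominator: zero score if the numerator also vanishes,
    # otherwise a large capped score
    spike = (~ok) & (num >= _DENOM_FLOOR)
    score[spike] = np.minimum(num[spike] / _DENOM_FLOOR, SCORE_CEILING)
    return score


def fisher_score(values, labels, denominator: str = "within_class") -> float:
    """Fisher score of a single gene's per-sample values."""
    return float(fisher_scores(np.asarray(values, dtype=float)[None, :],
                               np.asarray(labels), denominator)[0])


def detect_inflection(scores, min_keep: int, max_keep: int) -> int:
    """Elbow of a non-increasing score curve by the max-chord-distance rule.

    Both axes are min-max normalized, a chord is drawn from the first to
    the last point, and the index with the largest perpendicular distance
    to the chord is returned, clamped into ``[min_keep, max_keep]`` (and to
    the curve length).  A degenerate curve (constant or exactly linear)
    has zero distance everywhere and yields ``min_keep``.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score curve")
    if np.any(np.diff(scores) > 1e-12):
        raise ValueError("scores must be sorted non-increasing")
    n = scores.size
    if n == 1:
        idx = 0
    else:
        x = np.linspace(0.0, 1.0, n)
        span = scores[0] - scores[-1]
        y = (scores - scores[-1]) / span if span > 0 else np.zeros(n)
        # chord from (0, y0) to (1, y_last): distance ~ |x + y - 1| since
        # after normalization the chord is the anti-diagonal
        dist = np.abs(x + y - 1.0)
        idx = int(np.argmax(dist)) if dist.max() > 1e-12 else 0
    return int(min(max(idx, min_keep), max_keep, n))


def rank_genes(mat: ExpressionMatrix, min_keep: int = 50, max_keep: int = 4000,
               denominator: str = "within_class",
               keep: int | None = None) -> FisherRanking:
    """Score all genes, sort descending and locate the elbow cut.

    Ties in score are broken by lexicographic gene id so the ranking is
    fully deterministic.  ``keep`` overrides the automatic elbow with a
    manual cut size.
    """
    labels = mat.require_labels()
    scores = fisher_scores(mat.values, labels, denominator)
    order = sorted(range(mat.n_genes), key=lambda i: (-scores[i], mat.gene_ids[i]))
    sorted_scores = scores[order]
    if keep is not None:
        cut = int(min(max(keep, 1), mat.n_genes))
    else:
        cut = detect_inflection(sorted_scores, min(min_keep, mat.n_genes), max_keep)
    return FisherRanking([mat.gene_ids[i] for i in order], sorted_scores, cut)


def apply_filter(mat: ExpressionMatrix, ranking: FisherRanking) -> ExpressionMatrix:
    """Restrict ``mat`` to the top-``d1`` ranked genes (matrix ``A_1``)."""
    if set(ranking.gene_ids) != set(mat.gene_ids):
        raise ValueError("ranking does not match the matrix it is applied to")
    return mat.subset_genes(ranking.kept_gene_ids)
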