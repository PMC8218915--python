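"""Synthetic labelled expression matrices with planted differential genes.

Emulates the shape of post-normalization microarray data: small sample
counts (tens per class), large gene counts (thousands to tens of
thousands), approximately Gaussian noise on the log2 scale, and a small
planted set of genes whose class-1 mean is shifted by a chosen effect
size.  Every stage of the pipeline can then be validated desk-side by
checking how much of the planted set is recovered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expression_io import LOG2, ExpressionMatrix


@dataclass
class SimConfig:
    """Generator settings.

    ``effect_size`` is the class-1 mean shift of informative genes in
    units of ``noise_sd``; ``baseline_mean`` is on the log2 scale (7.0
    sits mid-range for typical normalized microarray intensities).
    ``t_df`` switches the noise to a scaled Student-t with that many
    degrees of freedom for heavier-tailed stress tests.
    """

    n_genes: int = 2000
    n_samples_per_class: tuple[int, int] = (30, 30)
    n_informative: int = 20
    effect_size: float = 2.0
    noise_sd: float = 1.0
    baseline_mean: float = 7.0
    seed: int = 0
    t_df: float | None = None

    def __post_init__(self) -> None:
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative cannot exceed n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if min(self.n_samples_per_class) < 1:
            raise ValueError("each class needs at least one sample")
        if self.t_df is not None and self.t_df <= 2:
            raise ValueError("t_df must exceed 2 for finite variance")


def simulate(cfg: SimConfig) -> tuple[ExpressionMatrix, list[str]]:
    """Draw a labelled matrix and return it with the planted gene ids.

    Background genes are ``Normal(baseline_mean, noise_sd)`` in both
    classes; the planted informative genes gain ``effect_size * noise_sd``
    in class 1.  Fully deterministic for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n0, n1 = cfg.n_samples_per_class
    m = n0 + n1
    if cfg.t_df is None:
        noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, m))
    else:
        scale = cfg.noise_sd * np.sqrt((cfg.t_df - 2) / cfg.t_df)
        noise = scale * rng.standard_t(cfg.t_df, size=(cfg.n_genes, m))
    values = cfg.baseline_mean + noise
    planted_idx = np.sort(rng.choice(cfg.n_genes, cfg.n_informative, replace=False))
    values[np.ix_(planted_idx, np.arange(n0, m))] += cfg.effect_size * cfg.noise_sd

    gene_ids = [f"G{i + 1:06d}" for i in range(cfg.n_genes)]
    sample_ids = [f"N{i + 1:03d}" for i in range(n0)] + \
                 [f"T{i + 1:03d}" for i in range(n1)]
    labels = np.r_[np.zeros(n0, dtype=int), np.ones(n1, dtype=int)]
    mat = ExpressionMatrix(gene_ids, sample_ids, values, labels=labels, scale=LOG2)
    return mat, [gene_ids[i] for i in planted_idx]


def recovery_score(selected, planted) -> float:
    """Fraction of planted genes present in the selected set."""
    planted = set(map(str, planted))
    if not planted:
        raise ValueError("planted set must be non-empty")
    return len(set(map(str, selected)) & planted) / len(planted)
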