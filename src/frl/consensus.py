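"""Cross-run / cross-dataset consensus of selected gene sets.

Biomarkers recurring across independent selections are more reliable than
single-run hits.  Selections (one per dataset, or one per repeated run)
are compared in pairs and every gene appearing in at least one pairwise
intersection joins the biomarker module, with a support count of how many
pairs it recurred in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

from .embedded_layer import FRLConfig, run_frl
from .expression_io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class SelectionCollection:
    """Named gene-id sets from repeated runs or multiple datasets."""

    entries: dict[str, frozenset[str]] = field(default_factory=dict)
    provenance: dict[str, dict] = field(default_factory=dict)

    def add(self, name: str, genes, **meta) -> None:
        if name in self.entries:
            raise ValueError(f"duplicate selection name {name!r}")
        genes = frozenset(map(str, genes))
        if not genes:
            raise ValueError(f"selection {name!r} is empty")
        self.entries[name] = genes
        self.provenance[name] = dict(meta)


@dataclass
class BiomarkerModule:
    """Genes recurring in pairwise intersections, with per-gene support."""

    genes: frozenset[str]
    support: dict[str, int]


def harmonize_gene_ids(genes) -> frozenset[str]:
    """Case-fold gene symbols for cross-dataset comparison."""
    return frozenset(str(g).strip().upper() for g in genes)


def pairwise_recurrence(sc: SelectionCollection, min_support: int = 1,
                        harmonize: bool = False) -> BiomarkerModule:
    """Extract genes recurring in pairwise intersections of the entries.

    A gene's support is the number of unordered entry pairs whose
    intersection contains it; genes with support >= ``min_support`` form
    the module.  With ``harmonize`` gene ids are case-folded first (for
    selections coming from differently annotated datasets).
    """
    if len(sc.entries) < 2:
        raise ValueError("need at least 2 selections to compare in pairs")
    sets = {name: (harmonize_gene_ids(genes) if harmonize else genes)
            for name, genes in sc.entries.items()}
    support: dict[str, int] = {}
    for a, b in combinations(sorted(sets), 2):
        for gene in sets[a] & sets[b]:
            support[gene] = support.get(gene, 0) + 1
    kept = {g: s for g, s in support.items() if s >= min_support}
    return BiomarkerModule(frozenset(kept), kept)


def stability_select(mat: ExpressionMatrix, cfg: FRLConfig,
                     n_repeats: int, seeds=None) -> SelectionCollection:
    """Run the full pipeline repeatedly and collect the selected subsets.

    Each repeat reruns ``run_frl`` with its own seed (``seeds`` defaults
    to ``cfg.seed, cfg.seed+1, ...``), so the fold assignment — the only
    stochastic ingredient — varies across repeats and the recurring genes
    are the stable core of the selection.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be at least 2")
    if seeds is None:
        seeds = [cfg.seed + i for i in range(n_repeats)]
    seeds = list(seeds)
    if len(seeds) != n_repeats:
        raise ValueError("seeds must match n_repeats")
    sc = SelectionCollection()
    for i, seed in enumerate(seeds):
        run_cfg = _with_seed(cfg, seed)
        _, path, _ = run_frl(mat, run_cfg)
        sc.add(f"run{i:03d}", path.selected_features, seed=seed)
    return sc


def _with_seed(cfg: FRLConfig, seed: int) -> FRLConfig:
    from dataclasses import replace
    return replace(cfg, seed=seed)
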