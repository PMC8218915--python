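"""Reading, collapsing and transforming labelled expression matrices.

The pipeline consumes background-corrected, normalized expression values
(e.g. RMA output from microarray data); normalization itself is an external
preprocessing step and is deliberately not re-implemented here.  What this
module does handle:

* parsing genes x samples matrices from plain TSV or the GEO
  series-matrix dialect,
* attaching binary sample labels (0 = normal, 1 = cancer),
* collapsing probe-level rows to one representative row per gene,
* the log2 transform applied before scoring.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LINEAR = "linear"
LOG2 = "log2"

_LABEL_ALIASES = {
    "0": 0, "normal": 0, "control": 0,
    "1": 1, "cancer": 1, "tumor": 1, "tumour": 1,
}


@dataclass
class ExpressionMatrix:
    """A labelled genes x samples numeric expression matrix.

    Parameters
    ----------
    gene_ids : list of str
        Unique row identifiers (genes, or probes before collapsing).
    sample_ids : list of str
        Unique column identifiers.
    values : ndarray of shape (n_genes, n_samples)
        Finite expression values.
    labels : ndarray of shape (n_samples,), optional
        Binary class per sample, 0 = normal and 1 = cancer.  ``None``
        until :func:`attach_labels` is called.
    scale : {"linear", "log2"}
        Tracks whether values are raw intensities or log2-transformed.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None
    scale: str = LINEAR

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")
        if self.scale not in (LINEAR, LOG2):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.sample_ids),):
                raise ValueError("labels length must equal sample count")
            if not set(np.unique(self.labels)) <= {0, 1}:
                raise ValueError("labels must be binary 0/1")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def require_labels(self) -> np.ndarray:
        """Return labels, insisting both classes are present."""
        if self.labels is None:
            raise ValueError("matrix has no labels; call attach_labels first")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("both classes must be present")
        return self.labels

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        """Restrict to ``gene_ids`` in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            list(gene_ids), list(self.sample_ids), self.values[rows],
            labels=None if self.labels is None else self.labels.copy(),
            scale=self.scale,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ProbeMap:
    """Many-to-one probe -> gene mapping.

    Probes absent from the mapping are dropped (with a logged count) when
    collapsing; a probe may map to exactly one gene.
    """

    mapping: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs) -> "ProbeMap":
        mapping: dict[str, str] = {}
        for probe, gene in pairs:
            probe, gene = str(probe), str(gene)
            if probe in mapping and mapping[probe] != gene:
                raise ValueError(f"probe {probe!r} maps to multiple genes")
            mapping[probe] = gene
        return cls(mapping)

    @classmethod
    def read(cls, path) -> "ProbeMap":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.shape[1] < 2:
            raise ValueError("probe map needs two columns: probe_id, gene_id")
        return cls.from_pairs(df.iloc[:, :2].itertuples(index=False))


def _frame_to_matrix(df: pd.DataFrame, path) -> ExpressionMatrix:
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r} in {path}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {df.iat[r, c]!r} at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r} in {path}"
        )
    values = numeric.to_numpy(dtype=float)
    gene_ids = [str(g) for g in df.index]
    # duplicate rows in a pre-collapsed matrix: keep the largest grand mean
    if len(set(gene_ids)) != len(gene_ids):
        order = np.argsort(-values.mean(axis=1), kind="stable")
        keep: dict[str, int] = {}
        for i in order:
            keep.setdefault(gene_ids[i], i)
        n_dropped = len(gene_ids) - len(keep)
        logger.warning("dropped %d duplicate gene rows (kept largest grand mean)", n_dropped)
        rows = sorted(keep.values())
        values = values[rows]
        gene_ids = [gene_ids[i] for i in rows]
    return ExpressionMatrix(gene_ids, [str(s) for s in df.columns], values)


def read_matrix(path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix from ``path``.

    ``dialect="tsv"``: header row of sample ids, first column gene/probe ids.
    ``dialect="series_matrix"``: GEO series-matrix file; only the table
    between the ``!series_matrix_table_begin`` / ``!series_matrix_table_end``
    sentinels is read, and quotes around identifiers are stripped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
        sample_ids = header.split("\t")[1:]
        # pandas would silently mangle duplicate column names, so check first
        if len(set(sample_ids)) != len(sample_ids):
            dup = next(s for s in sample_ids if sample_ids.count(s) > 1)
            raise ValueError(f"duplicate sample id {dup!r} in {path}")
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        df.columns = sample_ids
    elif dialect == "series_matrix":
        lines = path.read_text().splitlines()
        try:
            begin = next(i for i, l in enumerate(lines)
                         if l.strip().lower().startswith("!series_matrix_table_begin"))
            end = next(i for i, l in enumerate(lines)
                       if l.strip().lower().startswith("!series_matrix_table_end"))
        except StopIteration:
            raise ValueError(f"{path}: missing series-matrix table sentinels") from None
        table = [
            [tok.strip().strip('"') for tok in line.split("\t")]
            for line in lines[begin + 1:end] if line.strip()
        ]
        if not table:
            raise ValueError(f"{path}: empty series-matrix table")
        header = table[0]
        df = pd.DataFrame([row[1:] for row in table[1:]],
                          index=[row[0] for row in table[1:]],
                          columns=header[1:])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _frame_to_matrix(df, path)


def write_matrix(mat: ExpressionMatrix, path) -> None:
    """Write the matrix as TSV (round-trips through :func:`read_matrix`)."""
    mat.to_frame().to_csv(path, sep="\t", float_format="%.12g")


def read_labels(path) -> dict[str, int]:
    """Read a two-column sample_id / label TSV ({0,1} or {normal,cancer})."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    first = str(df.iat[0, 1]).strip().lower()
    if first not in _LABEL_ALIASES:  # tolerate a header row
        df = df.iloc[1:]
    out: dict[str, int] = {}
    for sample, raw in df.iloc[:, :2].itertuples(index=False):
        key = str(raw).strip().lower()
        if key not in _LABEL_ALIASES:
            raise ValueError(f"unrecognized label {raw!r} for sample {sample!r}")
        out[str(sample)] = _LABEL_ALIASES[key]
    return out


def attach_labels(mat: ExpressionMatrix, labels) -> ExpressionMatrix:
    """Return a copy of ``mat`` with labels attached.

    ``labels`` is a mapping sample_id -> label (ints, or names like
    "normal"/"cancer"), or a path to a two-column TSV.
    """
    if isinstance(labels, (str, Path)):
        labels = read_labels(labels)
    resolved = []
    for s in mat.sample_ids:
        if s not in labels:
            raise KeyError(f"no label for sample {s!r}")
        raw = labels[s]
        key = str(raw).strip().lower()
        if key not in _LABEL_ALIASES:
            raise ValueError(f"unrecognized label {raw!r} for sample {s!r}")
        resolved.append(_LABEL_ALIASES[key])
    return ExpressionMatrix(list(mat.gene_ids), list(mat.sample_ids),
                            mat.values.copy(), labels=np.array(resolved),
                            scale=mat.scale)


_GROUP_SUFFIX = re.compile(r"^(?P<prefix>.+)\.(\d+)$")


def probe_group_key(probe_id: str) -> str:
    """Probe-set grouping convention.

    Probes that differ only in a trailing ``.<number>`` suffix are treated
    as one probe group (e.g. ``201234_at.1`` / ``201234_at.2``); any other
    probe id forms its own singleton group.
    """
    m = _GROUP_SUFFIX.match(probe_id)
    return m.group("prefix") if m else probe_id


def collapse_probes(mat: ExpressionMatrix, pm: ProbeMap) -> ExpressionMatrix:
    """Collapse probe-level rows to one representative row per gene.

    Probes mapping to a gene are partitioned into probe groups
    (:func:`probe_group_key`), each group is averaged per sample, and the
    group with the largest grand-mean expression represents the gene
    (ties broken by lexicographically smallest group key).  Unmapped
    probes are dropped with a logged count.
    """
    mapped_rows: dict[str, dict[str, list[int]]] = {}
    gene_order: list[str] = []
    n_unmapped = 0
    for i, probe in enumerate(mat.gene_ids):
        gene = pm.mapping.get(probe)
        if gene is None:
            n_unmapped += 1
            continue
        if gene not in mapped_rows:
            mapped_rows[gene] = {}
            gene_order.append(gene)
        mapped_rows[gene].setdefault(probe_group_key(probe), []).append(i)
    if n_unmapped:
        logger.info("dropped %d unmapped probes", n_unmapped)
    if not mapped_rows:
        raise ValueError("no probes in the matrix are present in the probe map")

    rows = np.empty((len(gene_order), mat.n_samples))
    for out_i, gene in enumerate(gene_order):
        best_key, best_row, best_mean = None, None, -np.inf
        for key in sorted(mapped_rows[gene]):
            group_row = mat.values[mapped_rows[gene][key]].mean(axis=0)
            group_mean = group_row.mean()
            if group_mean > best_mean:
                best_key, best_row, best_mean = key, group_row, group_mean
        rows[out_i] = best_row
    return ExpressionMatrix(gene_order, list(mat.sample_ids), rows,
                            labels=None if mat.labels is None else mat.labels.copy(),
                            scale=mat.scale)


def log2_transform(mat: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """Return ``log2(values + offset)`` with the scale flag set to log2.

    Raises if the matrix is already log2-scaled, or if any shifted value is
    non-positive (set ``offset`` — commonly 1 — to handle zeros).
    """
    if mat.scale == LOG2:
        raise ValueError("matrix already transformed to log2 scale")
    shifted = mat.values + offset
    if np.any(shifted <= 0):
        raise ValueError(
            "non-positive values under the current offset; "
            "set a positive log offset (commonly 1)"
        )
    return ExpressionMatrix(list(mat.gene_ids), list(mat.sample_ids),
                            np.log2(shifted),
                            labels=None if mat.labels is None else mat.labels.copy(),
                            scale=LOG2)
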