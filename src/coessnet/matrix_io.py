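"""Reading, orienting, aligning and writing fitness matrices and edge tables.

The canonical in-memory orientation is genes x cell lines: the gene
knockout fitness profile (one row) is the unit of analysis everywhere
downstream. DepMap portal exports are cell lines x genes, so the loader
can auto-transpose based on the ``ACH-``-prefixed cell-line identifiers.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_CELL_LINE_RE = re.compile(r"ACH-\d{6}")


@dataclass(frozen=True)
class FitnessMatrix:
    """A gene x cell-line matrix of knockout fitness scores.

    ``data`` is a pandas DataFrame indexed by gene symbol with cell-line
    identifiers as columns. Scores may be Bayes Factors, Ceres/Chronos
    gene effects, or Z-scores; the pipeline is agnostic to the scheme.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        dup_genes = idx[idx.duplicated()].unique().tolist()
        if dup_genes:
            raise ValueError(f"duplicate gene ids: {dup_genes}")
        dup_samples = cols[cols.duplicated()].unique().tolist()
        if dup_samples:
            raise ValueError(f"duplicate sample ids: {dup_samples}")
        if self.data.isna().any().any():
            raise ValueError("FitnessMatrix may not contain missing values")

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: Sequence[str]) -> "FitnessMatrix":
        return FitnessMatrix(self.data.loc[list(genes)])


def _strip_entrez(label: str) -> str:
    """DepMap labels genes as ``SYMBOL (EntrezID)``; keep the symbol."""
    return str(label).split(" ", 1)[0]


def load_fitness_matrix(path, orientation: str = "auto") -> FitnessMatrix:
    """Load a delimited score table into canonical genes x samples form.

    Parameters
    ----------
    path
        Delimited text file (comma or tab, sniffed) with one header row
        and row labels in the first column.
    orientation
        ``genes_by_samples``, ``samples_by_genes``, or ``auto``. Auto
        transposes when at least 80% of the row labels look like DepMap
        cell-line identifiers (``ACH-``) and the column labels do not.

    Rows (genes) containing any missing value are dropped with a warning.
    """
    if orientation not in ("genes_by_samples", "samples_by_genes", "auto"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no data columns")
    for c in df.columns:
        coerced = pd.to_numeric(df[c], errors="coerce")
        if coerced.isna().all() and not df[c].isna().all():
            raise ValueError(f"{path}: column {c!r} is fully non-numeric")
        df[c] = coerced

    if orientation == "auto":
        rows_look_like_lines = _frac_cell_line_labels(df.index)
        cols_look_like_lines = _frac_cell_line_labels(df.columns)
        if rows_look_like_lines >= 0.8 and cols_look_like_lines < 0.8:
            df = df.T
    elif orientation == "samples_by_genes":
        df = df.T

    df.index = [_strip_entrez(g) for g in df.index]
    df.columns = [str(c) for c in df.columns]

    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        dropped = df.index[df.isna().any(axis=1)].tolist()
        logger.warning("dropping %d gene rows with missing values: %s",
                       n_missing, dropped[:10])
        df = df.dropna(axis=0)
    return FitnessMatrix(df)


def _frac_cell_line_labels(labels: Iterable) -> float:
    labels = [str(x) for x in labels]
    if not labels:
        return 0.0
    return sum(bool(_CELL_LINE_RE.search(x)) for x in labels) / len(labels)


def intersect_matrices(matrices: Sequence[FitnessMatrix]) -> list[FitnessMatrix]:
    """Restrict all matrices to their common genes and samples.

    Labels are matched on gene symbol / cell-line identifier; the outputs
    share identical, lexicographically sorted axes.
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 matrices to intersect")
    genes = set(matrices[0].gene_ids)
    samples = set(matrices[0].sample_ids)
    for m in matrices[1:]:
        genes &= set(m.gene_ids)
        samples &= set(m.sample_ids)
    if not genes or not samples:
        raise ValueError("empty gene or sample intersection")
    genes_sorted = sorted(genes)
    samples_sorted = sorted(samples)
    return [FitnessMatrix(m.data.loc[genes_sorted, samples_sorted]) for m in matrices]


def write_edge_table(ranking, path) -> None:
    """Write a ranked pair list as a Cytoscape-importable TSV edge table.

    Columns: gene_a, gene_b, score, rank; gene_a < gene_b lexicographically.
    """
    edges = ranking.edges
    if len(edges) == 0:
        raise ValueError("empty ranking")
    out = edges[["gene_a", "gene_b", "score", "rank"]].copy()
    swap = out["gene_a"] > out["gene_b"]
    out.loc[swap, ["gene_a", "gene_b"]] = out.loc[swap, ["gene_b", "gene_a"]].to_numpy()
    out.to_csv(path, sep="\t", index=False)
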